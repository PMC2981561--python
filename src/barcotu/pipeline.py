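"""End-to-end barcoding pipeline: from sequences to named OTUs and reports.

Stage order::

    read -> trim/frame -> pseudogene & paralogue QC -> drop clone libraries
         -> dereplicate environmental records -> distance matrix
         -> calibration diagnostics -> species & genus OTUs
         -> ambiguity resolution -> naming -> identification & summaries
         -> NJ clustergram & PCoA

Each stage consumes the previous stage's products only; a failed stage
aborts the run with a clear error rather than cascading.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from .calibrate import TaxonExclusions, calibrate, genus_bound_table
from .cluster import (
    cluster_threshold,
    name_otus,
    partition_frame,
    resolve_ambiguous,
    validate_partition,
)
from .distance import DistanceMatrix, distance_matrix
from .identify import (
    family_case_report,
    identify_queries,
    results_frame,
    summarize_diversity,
)
from .qc import QcConfig, paralogue_reports, screen_pseudogenes
from .trees import nj_tree, pcoa
from .io import BarcodeDataset, read_dataset, trim_to_common_frame, dereplicate

logger = logging.getLogger("barcotu")


@dataclass(frozen=True)
class RunConfig:
    """Knobs of a pipeline run; defaults are the survey settings."""

    species_cutoff: float = 0.24
    genus_threshold: float = 1.4
    default_genus_bound: float = 1.4
    borderline_upper: float = 0.27
    min_overlap: int = 100
    genetic_code_id: int = 4
    editing_sites: tuple[int, ...] = ()
    anchor_id: str | None = None
    family_reference_genera: tuple[str, ...] = ()
    family_bound: float = 5.9
    calibration_cutoffs: tuple[float, ...] = (0.24,)
    pcoa_standardize: str = "none"
    make_tree: bool = True
    make_pcoa: bool = True


@dataclass
class PipelineResult:
    dataset: BarcodeDataset  # trimmed, QC-passed, dereplicated working set
    multiplicity: dict[str, list[str]]
    matrix: DistanceMatrix
    pseudogene_failures: list[str]
    paralogue_reports: list
    calibration_all: object
    calibration_excluded: object
    genus_bounds: dict[str, float]
    species_partition: object
    genus_partition: object
    otu_names: dict[str, str]
    identifications: list
    summary: object
    family_report: object | None = None
    tree: object | None = None
    pcoa: object | None = None
    manifest: dict = field(default_factory=dict)


def run_pipeline(
    dataset: BarcodeDataset,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage over an untrimmed dataset and optionally write outputs."""
    cfg = config or RunConfig()
    t0 = time.time()
    manifest: dict = {"stages": []}

    def stage(name):
        manifest["stages"].append({"name": name, "t": round(time.time() - t0, 2)})
        logger.info("stage: %s", name)

    stage("trim_and_frame")
    data = trim_to_common_frame(
        dataset, genetic_code_id=cfg.genetic_code_id, min_window=cfg.min_overlap
    )

    stage("pseudogene_screen")
    qc_cfg = QcConfig(
        genetic_code_id=cfg.genetic_code_id, editing_sites=set(cfg.editing_sites)
    )
    verdicts = screen_pseudogenes(data, qc_cfg)
    failures = sorted(rid for rid, v in verdicts.items() if not v.passed)
    if failures:
        logger.warning("removing %d putative pseudogenes", len(failures))

    stage("paralogue_test")
    paralogues = paralogue_reports(data, qc_cfg, min_overlap=cfg.min_overlap)

    # clone-library records exist for the paralogue screen only; the survey
    # proper runs on cultured + environmental records that passed QC
    keep = [
        r.record_id
        for r in data.records
        if r.record_id not in set(failures) and r.source_class != "clone"
    ]
    data = data.subset(keep)

    stage("dereplicate")
    data, multiplicity = dereplicate(data, scope="environmental_only")

    stage("distance_matrix")
    matrix = distance_matrix(data, min_overlap=cfg.min_overlap)

    stage("calibration")
    references = [r for r in data.records if r.source_class == "cultured"]
    try:
        cal_all = calibrate(
            matrix, references, TaxonExclusions.none(), cfg.calibration_cutoffs
        )
        cal_excl = calibrate(
            matrix, references, TaxonExclusions.default(), cfg.calibration_cutoffs
        )
        genus_bounds = genus_bound_table(cal_all, default=cfg.default_genus_bound)
    except ValueError as exc:
        logger.warning("calibration skipped: %s", exc)
        cal_all = cal_excl = None
        genus_bounds = {}

    stage("species_otus")
    species = cluster_threshold(matrix, cfg.species_cutoff, "species")
    species = resolve_ambiguous(species, matrix)
    validate_partition(species, matrix)

    stage("genus_otus")
    genus = cluster_threshold(matrix, cfg.genus_threshold, "genus")
    genus = resolve_ambiguous(genus, matrix)
    validate_partition(genus, matrix)

    stage("naming")
    family_ids = {
        r.record_id
        for r in references
        if r.genus in set(cfg.family_reference_genera)
    }
    if cfg.anchor_id:
        family_ids.add(cfg.anchor_id)
    names = name_otus(
        species, genus, data, anchor_id=cfg.anchor_id, family_ids=family_ids
    )

    stage("identification")
    queries = [
        r.record_id
        for r in data.records
        if r.source_class in ("environmental", "single_cell")
    ]
    results = identify_queries(
        queries,
        references,
        species,
        genus,
        matrix,
        genus_bounds=genus_bounds,
        otu_names=names,
        default_genus_bound=cfg.default_genus_bound,
        species_cutoff=cfg.species_cutoff,
        borderline_upper=cfg.borderline_upper,
    )
    summary = summarize_diversity(results, species, multiplicity, data, references)

    family_report = None
    if cfg.anchor_id and family_ids:
        stage("family_case")
        family_report = family_case_report(
            species,
            genus,
            matrix,
            queries,
            multiplicity,
            family_ids,
            cfg.anchor_id,
            family_bound=cfg.family_bound,
        )

    tree = None
    if cfg.make_tree and len(matrix) >= 2:
        stage("nj_tree")
        tree = nj_tree(matrix)

    pcoa_result = None
    if cfg.make_pcoa and len(matrix) >= 2:
        stage("pcoa")
        pcoa_result = pcoa(matrix, standardize=cfg.pcoa_standardize)

    manifest["n_input_records"] = len(dataset)
    manifest["n_working_records"] = len(data)
    manifest["n_pseudogene_failures"] = len(failures)
    manifest["runtime_s"] = round(time.time() - t0, 2)

    result = PipelineResult(
        dataset=data,
        multiplicity=multiplicity,
        matrix=matrix,
        pseudogene_failures=failures,
        paralogue_reports=paralogues,
        calibration_all=cal_all,
        calibration_excluded=cal_excl,
        genus_bounds=genus_bounds,
        species_partition=species,
        genus_partition=genus,
        otu_names=names,
        identifications=results,
        summary=summary,
        family_report=family_report,
        tree=tree,
        pcoa=pcoa_result,
        manifest=manifest,
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def run_pipeline_files(
    fasta_path, metadata_path, config: RunConfig | None = None, out_dir=None
) -> PipelineResult:
    """Convenience wrapper: read FASTA + metadata, then run the pipeline."""
    dataset = read_dataset(fasta_path, metadata_path)
    return run_pipeline(dataset, config, out_dir)


def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    """Write the run's tables, trees, coordinates and manifest to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    partition_frame(result.species_partition, result.otu_names).to_csv(
        out / "species_otus.tsv", sep="\t", index=False
    )
    partition_frame(result.genus_partition).to_csv(
        out / "genus_otus.tsv", sep="\t", index=False
    )
    results_frame(result.identifications).to_csv(
        out / "identifications.tsv", sep="\t", index=False
    )
    if result.calibration_all is not None:
        result.calibration_all.scatter_frame().to_csv(
            out / "calibration_pwds.tsv", sep="\t", index=False
        )

    summary = result.summary.to_dict()
    summary["pseudogene_failures"] = result.pseudogene_failures
    summary["paralogue_flags"] = [
        r.strain_id for r in result.paralogue_reports if r.flagged
    ]
    if result.calibration_all is not None:
        summary["assignable_fraction_all"] = result.calibration_all.assignable_fraction
        summary["assignable_fraction_after_exclusions"] = (
            result.calibration_excluded.assignable_fraction
        )
    if result.family_report is not None:
        summary["family_case"] = {
            "clones_in_family": result.family_report.clones_in_family,
            "genus_level_with_anchor": result.family_report.genus_level_with_anchor,
            "species_level_with_anchor": result.family_report.species_level_with_anchor,
            "species_otus_with_anchor": result.family_report.species_otus_with_anchor,
        }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)

    if result.tree is not None:
        (out / "nj_clustergram.nwk").write_text(result.tree.to_newick() + "\n")
    if result.pcoa is not None:
        result.pcoa.frame().to_csv(out / "pcoa_coordinates.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)
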