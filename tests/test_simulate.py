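"""Synthetic data generator: determinism, planted geometry, truth recovery."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from barcotu.cluster import cluster_threshold
from barcotu.distance import distance_matrix
from barcotu.io import dereplicate, trim_to_common_frame
from barcotu.qc import QcConfig, paralogue_reports, screen_pseudogenes
from barcotu.simulate import (
    EnvironmentalConfig,
    GenerationError,
    GeneratorConfig,
    generate,
    paper_scale_profile,
)


def fingerprint(dataset):
    return [(r.record_id, r.sequence, r.source_class, r.strain_id)
            for r in dataset.records]


def test_generic_byte_determinism():
    a, ta = generate(GeneratorConfig(seed=5))
    b, tb = generate(GeneratorConfig(seed=5))
    assert fingerprint(a) == fingerprint(b)
    assert ta.species_otu == tb.species_otu
    assert ta.duplicate_map == tb.duplicate_map


def test_generic_seed_changes_sequences_not_structure():
    a, ta = generate(GeneratorConfig(seed=1))
    b, tb = generate(GeneratorConfig(seed=2))
    assert len(a.records) == len(b.records)
    assert [r.record_id for r in a.records] == [r.record_id for r in b.records]
    assert any(x.sequence != y.sequence for x, y in zip(a.records, b.records))
    assert len(set(ta.species_otu.values())) == len(set(tb.species_otu.values()))


def test_generic_planted_geometry_and_recovery():
    ds, truth = generate(GeneratorConfig(seed=3))
    m = distance_matrix(ds)
    part = cluster_threshold(m, 0.24)
    found = [part.assignments[r] for r in m.ids]
    planted = [truth.species_otu[r] for r in m.ids]
    assert adjusted_rand_score(planted, found) == 1.0
    genus = cluster_threshold(m, 1.4, level="genus")
    found_g = [genus.assignments[r] for r in m.ids]
    planted_g = [truth.genus_otu[r] for r in m.ids]
    assert adjusted_rand_score(planted_g, found_g) == 1.0


def test_generic_frame_offset_recovered():
    cfg = GeneratorConfig(seed=4, frame_offset=2)
    ds, truth = generate(cfg)
    assert truth.frame_offset == 2
    trimmed = trim_to_common_frame(ds)
    assert trimmed.frame_offset == 2


def test_generic_pseudogenes_and_paralogues_planted():
    cfg = GeneratorConfig(
        seed=6, pseudogene_rate=0.05, paralogue_strains=2,
        environmental=EnvironmentalConfig(n_clones=40),
    )
    ds, truth = generate(cfg)
    assert truth.pseudogenes
    qc = QcConfig(editing_sites=set(truth.editing_sites))
    verdicts = screen_pseudogenes(ds, qc)
    failed = {rid for rid, v in verdicts.items() if not v.passed}
    assert failed == set(truth.pseudogenes)
    reports = paralogue_reports(ds, qc)
    flagged = {r.strain_id for r in reports if r.flagged}
    assert flagged == truth.paralogue_strains
    assert len(truth.paralogue_strains) == 2


def test_generic_regimes_still_recoverable():
    cfg = GeneratorConfig(
        seed=7, n_genera=8,
        regimes=frozenset(
            {"low_divergence_genus", "hyperdiverse_clades",
             "cryptic_complex", "split_genus"}
        ),
    )
    ds, truth = generate(cfg)
    m = distance_matrix(ds)
    part = cluster_threshold(m, 0.24)
    planted = [truth.species_otu[r] for r in m.ids]
    found = [part.assignments[r] for r in m.ids]
    assert adjusted_rand_score(planted, found) == 1.0


def test_environmental_mixture_and_duplicates():
    cfg = GeneratorConfig(
        seed=8, environmental=EnvironmentalConfig(n_clones=60)
    )
    ds, truth = generate(cfg)
    env = [r for r in ds.records
           if r.source_class in ("environmental", "single_cell")]
    assert len(env) == 60
    derep, mult = dereplicate(ds, scope="environmental_only")
    reps = {k for k, v in mult.items() if len(v) > 1}
    truth_reps = {k for k, v in truth.duplicate_map.items() if len(v) > 1}
    assert reps == truth_reps
    linked = [rid for rid, s in truth.statuses.items() if s == "species_match"]
    assert linked  # mixture contains reference-linked clones


def test_config_validation_errors():
    with pytest.raises(GenerationError):
        GeneratorConfig(intra_species_pwd=(0.5, 0.24))
    with pytest.raises(GenerationError):
        GeneratorConfig(intra_species_pwd=(0.0, 2.0), inter_species_pwd=(0.3, 8.0))
    with pytest.raises(GenerationError):
        GeneratorConfig(frame_offset=3)
    with pytest.raises(GenerationError):
        generate(GeneratorConfig(profile="bogus"))


@pytest.fixture(scope="module")
def paper_scale():
    return generate(paper_scale_profile(seed=0))


def test_paper_scale_headline_structure(paper_scale):
    ds, truth = paper_scale
    e = truth.expected
    refs = [r for r in ds.records if r.source_class == "cultured"]
    named = [r for r in refs if r.is_named]
    assert len(refs) == e["n_references"] == 336
    assert len(named) == e["n_named_reference_strains"] == 189
    env = [r for r in ds.records
           if r.source_class in ("environmental", "single_cell")]
    assert len(env) == e["n_env_clones"] == 713
    uniques = {min(v) for v in truth.duplicate_map.values()}
    assert len(uniques) == e["n_env_unique"] == 603
    statuses = [truth.statuses[u] for u in uniques]
    assert statuses.count("species_match") == e["n_species_linked_uniques"] == 51
    assert statuses.count("genus_match") == e["n_genus_linked_uniques"] == 30
    assert e["anchor_id"] in {r.record_id for r in refs}
    assert truth.paralogue_strains == {e["paralogue_strain"]}


def test_paper_scale_metadata_and_clones(paper_scale):
    ds, truth = paper_scale
    env = [r for r in ds.records
           if r.source_class in ("environmental", "single_cell")]
    sites = {r.site for r in env}
    assert "Saanich Inlet" in sites and len(sites) >= 3
    single_cells = [r for r in env if r.source_class == "single_cell"]
    assert single_cells and all(r.site == "Vancouver Island" for r in single_cells)
    clones = [r for r in ds.records if r.source_class == "clone"]
    assert clones
    assert all(r.clone_parent for r in clones)


def test_paper_scale_determinism(paper_scale):
    ds, truth = paper_scale
    again, truth2 = generate(paper_scale_profile(seed=0))
    assert fingerprint(ds) == fingerprint(again)
    assert truth.expected == truth2.expected
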