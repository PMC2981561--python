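"""Identification of environmental barcodes against the reference library.

Each environmental (or single-cell) query is placed by group membership,
not nearest neighbour alone:

* ``species_match`` — the query shares a species-level OTU (complete
  linkage at 0.24%) with at least one named cultured reference.
* ``genus_match`` — the query shares a genus-level OTU with named
  references and is within that genus's empirical bound of every reference
  member of the OTU (bounds vary by genus; 1.4% default).
* ``unidentified`` — neither; the query receives an environmental-barcode
  (EB) label from the naming scheme.

Distances just above the species cut-off (0.24–0.27%) are flagged
``borderline``: close enough to deserve scrutiny, not close enough to bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import OtuPartition
from .distance import DistanceMatrix
from .io import BarcodeDataset, BarcodeRecord

SPECIES_CUTOFF = 0.24
BORDERLINE_UPPER = 0.27


@dataclass(frozen=True)
class IdentificationResult:
    query_id: str
    status: str  # species_match | genus_match | unidentified
    matched_name: str
    nearest_reference: str
    nearest_pwd: float
    borderline: bool


@dataclass
class DiversitySummary:
    """Headline diversity counts, on unique sequences and on raw clones."""

    n_total: int
    n_unique: int
    n_species_otus: int
    n_species_linked: int
    n_genus_linked: int
    pct_unknown_species: float
    clone_counts: dict[str, int] = field(default_factory=dict)
    breakdowns: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_unique": self.n_unique,
            "n_species_otus": self.n_species_otus,
            "n_species_linked": self.n_species_linked,
            "n_genus_linked": self.n_genus_linked,
            "pct_unknown_species": self.pct_unknown_species,
            "clone_counts": self.clone_counts,
        }


def _named_reference_ids(references: list[BarcodeRecord]) -> set[str]:
    return {r.record_id for r in references if r.source_class == "cultured" and r.is_named}


def identify_queries(
    queries: list[str],
    references: list[BarcodeRecord],
    species_partition: OtuPartition,
    genus_partition: OtuPartition,
    matrix: DistanceMatrix,
    genus_bounds: dict[str, float] | None = None,
    otu_names: dict[str, str] | None = None,
    default_genus_bound: float = 1.4,
    species_cutoff: float = SPECIES_CUTOFF,
    borderline_upper: float = BORDERLINE_UPPER,
) -> list[IdentificationResult]:
    """Assign a status to every query id.

    ``queries`` are record ids present in both partitions and the matrix;
    a missing query is an error.  ``otu_names`` (from the naming scheme)
    supplies EB labels for unidentified queries and display names for
    matches.
    """
    genus_bounds = genus_bounds or {}
    otu_names = otu_names or {}
    named_ids = _named_reference_ids(references)
    by_id = {r.record_id: r for r in references}

    ref_list = sorted(named_ids & set(matrix.ids))
    ref_idx = np.array([matrix.index(r) for r in ref_list]) if ref_list else None

    results = []
    for q in queries:
        if q not in species_partition.assignments or q not in genus_partition.assignments:
            raise KeyError(f"query {q!r} missing from OTU partitions")
        qi = matrix.index(q)
        if ref_idx is not None and len(ref_idx):
            dists = matrix.d[qi, ref_idx]
            k = int(np.argmin(dists))
            nearest_ref, nearest_pwd = ref_list[k], float(dists[k])
        else:
            nearest_ref, nearest_pwd = "", float("nan")

        sp_otu = species_partition.assignments[q]
        sp_members = set(species_partition.otu_members[sp_otu])
        g_otu = genus_partition.assignments[q]
        g_members = set(genus_partition.otu_members[g_otu])

        if sp_members & named_ids:
            name = otu_names.get(sp_otu) or _consensus_name(sp_members & named_ids, by_id)
            results.append(
                IdentificationResult(q, "species_match", name, nearest_ref, nearest_pwd, False)
            )
            continue

        named_in_genus = sorted(g_members & named_ids)
        if named_in_genus:
            genera = sorted({by_id[r].genus for r in named_in_genus if r in by_id})
            bound = max(
                (genus_bounds.get(g, default_genus_bound) for g in genera),
                default=default_genus_bound,
            )
            midx = np.array([matrix.index(r) for r in named_in_genus])
            if float(matrix.d[qi, midx].max()) <= bound:
                results.append(
                    IdentificationResult(
                        q, "genus_match", "/".join(genera), nearest_ref, nearest_pwd, False
                    )
                )
                continue

        borderline = species_cutoff < nearest_pwd <= borderline_upper
        label = otu_names.get(sp_otu, "")
        results.append(
            IdentificationResult(q, "unidentified", label, nearest_ref, nearest_pwd, borderline)
        )
    return results


def _consensus_name(ref_ids: set[str], by_id: dict) -> str:
    names = sorted(
        {
            f"{by_id[r].genus} {by_id[r].species}"
            if by_id[r].species
            else f"{by_id[r].genus} clade {by_id[r].clade}"
            for r in ref_ids
            if r in by_id
        }
    )
    return "/".join(names)


def results_frame(results: list[IdentificationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "query_id": r.query_id,
                "status": r.status,
                "matched_name": r.matched_name,
                "nearest_reference": r.nearest_reference,
                "nearest_pwd": r.nearest_pwd,
                "borderline": r.borderline,
            }
            for r in results
        ]
    )


def summarize_diversity(
    results: list[IdentificationResult],
    species_partition: OtuPartition,
    multiplicity: dict[str, list[str]],
    dataset: BarcodeDataset,
    references: list[BarcodeRecord],
) -> DiversitySummary:
    """Headline diversity counts over the environmental survey.

    ``results`` covers the unique environmental queries; ``multiplicity``
    (from dereplication) maps each representative to its clone members so
    clone-level counts can be reported alongside unique-level counts.
    Site/depth/season cross-tabulations are computed from the metadata of
    all clones.
    """
    named_ids = _named_reference_ids(references)
    uniques = [r.query_id for r in results]
    mult = {q: len(multiplicity.get(q, [q])) for q in uniques}
    n_unique = len(uniques)
    n_total = sum(mult.values())

    env_otus = {species_partition.assignments[q] for q in uniques}
    n_species_otus = len(env_otus)
    linked_otus = {
        o for o in env_otus if set(species_partition.otu_members[o]) & named_ids
    }
    status = {r.query_id: r.status for r in results}
    species_linked = [q for q in uniques if status[q] == "species_match"]
    genus_linked = [q for q in uniques if status[q] == "genus_match"]
    pct_unknown = (
        100.0 * (n_species_otus - len(linked_otus)) / n_species_otus
        if n_species_otus
        else 0.0
    )

    clone_counts = {
        "species_match": sum(mult[q] for q in species_linked),
        "genus_match": sum(mult[q] for q in genus_linked),
        "unidentified": sum(
            mult[q] for q in uniques if status[q] == "unidentified"
        ),
    }

    # site/depth/season breakdowns at the clone level
    by_id = {r.record_id: r for r in dataset.records}
    rows = []
    for q in uniques:
        for member in multiplicity.get(q, [q]):
            rec = by_id.get(member, by_id.get(q))
            if rec is None:
                continue
            rows.append(
                {
                    "site": rec.site or "unknown",
                    "depth_m": rec.depth_m if rec.depth_m is not None else -1,
                    "season": rec.season,
                    "status": status[q],
                }
            )
    breakdowns = {}
    if rows:
        frame = pd.DataFrame(rows)
        for key in ("site", "depth_m", "season"):
            breakdowns[key] = (
                frame.groupby([key, "status"]).size().unstack(fill_value=0)
            )

    return DiversitySummary(
        n_total=n_total,
        n_unique=n_unique,
        n_species_otus=n_species_otus,
        n_species_linked=len(species_linked),
        n_genus_linked=len(genus_linked),
        pct_unknown_species=pct_unknown,
        clone_counts=clone_counts,
        breakdowns=breakdowns,
    )


@dataclass(frozen=True)
class FamilyCaseReport:
    clones_in_family: int
    genus_level_with_anchor: int
    species_level_with_anchor: int
    species_otus_with_anchor: int


def family_case_report(
    species_partition: OtuPartition,
    genus_partition: OtuPartition,
    matrix: DistanceMatrix,
    queries: list[str],
    multiplicity: dict[str, list[str]],
    family_members: set[str],
    anchor: str,
    family_bound: float = 5.9,
) -> FamilyCaseReport:
    """Clone-level counts for a family-scale environmental expansion.

    A query belongs to the family when its minimum distance to any family
    reference is within ``family_bound`` percent (the upper end of
    congeneric divergence).  Anchor-linked counts use shared genus- and
    species-level OTU membership with the anchor strain; the species-OTU
    count reports how many distinct species the anchor-linked clones
    represent.
    """
    if anchor not in matrix._index:
        raise KeyError(f"anchor {anchor!r} not in distance matrix")
    fam = sorted((family_members | {anchor}) & set(matrix.ids))
    fam_idx = np.array([matrix.index(f) for f in fam])
    mult = {q: len(multiplicity.get(q, [q])) for q in queries}

    anchor_sp = species_partition.assignments.get(anchor)
    anchor_g = genus_partition.assignments.get(anchor)

    clones_in_family = 0
    genus_level = 0
    species_level = 0
    anchor_linked_otus: set[str] = set()
    for q in queries:
        qi = matrix.index(q)
        if float(matrix.d[qi, fam_idx].min()) <= family_bound:
            clones_in_family += mult[q]
        if genus_partition.assignments.get(q) == anchor_g:
            genus_level += mult[q]
            anchor_linked_otus.add(species_partition.assignments[q])
        if species_partition.assignments.get(q) == anchor_sp:
            species_level += mult[q]
    return FamilyCaseReport(
        clones_in_family=clones_in_family,
        genus_level_with_anchor=genus_level,
        species_level_with_anchor=species_level,
        species_otus_with_anchor=len(anchor_linked_otus),
    )
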