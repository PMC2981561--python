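"""Species- and genus-level OTU delineation by complete-linkage clustering.

An OTU is a cluster of barcodes whose *maximum* intra-cluster p-distance
does not exceed a threshold: 0.24% at the species level, 1.4% by default at
the genus level.  Complete linkage (rather than single linkage) is required
because the genus rule demands that every member be within the threshold of
every other member, not merely chained through intermediates.

Agglomeration merges the pair of clusters with the smallest complete-linkage
(maximum cross) distance first, inclusive at the threshold boundary, with
ties broken by the lexicographically smallest member id so that output is
independent of input order.

Records that sit within the threshold of more than one OTU, or of only part
of their own, are "ambiguous": they are split off and re-grouped among
themselves, ending up in smaller groups or as singletons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .distance import DistanceMatrix


@dataclass
class OtuPartition:
    """Assignment of records to OTUs at one level/threshold."""

    level: str  # "species" or "genus"
    threshold: float  # percent, inclusive
    assignments: dict[str, str]  # record_id -> otu_id
    otu_members: dict[str, list[str]]  # otu_id -> sorted member ids
    ambiguous: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        n = sum(len(v) for v in self.otu_members.values())
        if n != len(self.assignments):
            raise ValueError("otu_members and assignments disagree")

    @property
    def n_otus(self) -> int:
        return len(self.otu_members)

    def otu_of(self, record_id: str) -> str:
        return self.assignments[record_id]

    def members_of(self, record_id: str) -> list[str]:
        return self.otu_members[self.assignments[record_id]]


def _finalize(level, threshold, clusters, ambiguous=()):
    """Build an OtuPartition from member lists with deterministic otu ids."""
    clusters = sorted((sorted(c) for c in clusters), key=lambda c: c[0])
    width = max(4, len(str(len(clusters))))
    otu_members, assignments = {}, {}
    for k, members in enumerate(clusters, start=1):
        otu_id = f"{level[0].upper()}OTU{k:0{width}d}"
        otu_members[otu_id] = members
        for rid in members:
            assignments[rid] = otu_id
    return OtuPartition(level, threshold, assignments, otu_members, set(ambiguous))


def cluster_threshold(
    matrix: DistanceMatrix, threshold: float, level: str = "species"
) -> OtuPartition:
    """Agglomerative complete-linkage clustering cut at ``threshold`` percent.

    Merging stops when no remaining merge keeps the maximum intra-cluster
    distance at or below the threshold, so every output OTU satisfies the
    complete-linkage invariant.  The boundary is inclusive ("0.24% or
    less").
    """
    if not np.isfinite(matrix.d).all():
        raise ValueError("distance matrix contains missing values")
    n = len(matrix.ids)
    if n == 0:
        return _finalize(level, threshold, [])
    if n == 1:
        return _finalize(level, threshold, [[matrix.ids[0]]])

    D = matrix.d.astype(float).copy()
    np.fill_diagonal(D, np.inf)
    active = np.ones(n, dtype=bool)
    members: list[list[str] | None] = [[rid] for rid in matrix.ids]
    # smallest member id per cluster, for tie-breaking
    min_id: list[str | None] = list(matrix.ids)

    while active.sum() > 1:
        m = D.min()
        if m > threshold:
            break
        ii, jj = np.nonzero(D == m)
        best = None
        for i, j in zip(ii, jj):
            if i >= j:
                continue
            key = tuple(sorted((min_id[i], min_id[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        members[i] = sorted(members[i] + members[j])
        min_id[i] = members[i][0]
        members[j] = None
        active[j] = False
        newrow = np.maximum(D[i], D[j])
        D[i, :] = newrow
        D[:, i] = newrow
        D[i, i] = np.inf
        D[j, :] = np.inf
        D[:, j] = np.inf

    return _finalize(level, threshold, [m for m in members if m is not None])


def validate_partition(partition: OtuPartition, matrix: DistanceMatrix) -> None:
    """Assert the complete-linkage invariant: max intra-OTU PWD <= threshold."""
    for otu_id, ids in partition.otu_members.items():
        if len(ids) < 2:
            continue
        sub = matrix.submatrix(ids).d
        worst = float(sub[np.triu_indices(len(ids), k=1)].max())
        if worst > partition.threshold + 1e-12:
            raise AssertionError(
                f"OTU {otu_id} violates complete linkage: "
                f"max intra PWD {worst:.4f} > {partition.threshold}"
            )


def resolve_ambiguous(partition: OtuPartition, matrix: DistanceMatrix) -> OtuPartition:
    """Split off records with conflicting threshold-level affinities.

    A record is ambiguous when it lies within the threshold of members of at
    least two distinct OTUs, or within the threshold of only a strict subset
    of its own OTU.  Ambiguous records are removed and re-grouped among
    themselves by complete-linkage clustering, remaining as smaller groups
    or singletons.
    """
    t = partition.threshold
    otu_ids = sorted(partition.otu_members)
    otu_code = {o: k for k, o in enumerate(otu_ids)}
    codes = np.array([otu_code[partition.assignments[rid]] for rid in matrix.ids])
    near = matrix.d <= t
    np.fill_diagonal(near, False)

    flagged: set[str] = set()
    for i, rid in enumerate(matrix.ids):
        own = codes[i]
        neighbor_codes = codes[near[i]]
        if (neighbor_codes != own).any():
            flagged.add(rid)
            continue
        own_mask = (codes == own) & (np.arange(len(codes)) != i)
        if own_mask.any() and not near[i][own_mask].all():
            flagged.add(rid)

    if not flagged:
        return replace(partition, ambiguous=set())

    kept = [
        [m for m in mem if m not in flagged]
        for mem in partition.otu_members.values()
    ]
    kept = [c for c in kept if c]
    sub = matrix.submatrix(sorted(flagged))
    regrouped = cluster_threshold(sub, t, partition.level)
    clusters = kept + list(regrouped.otu_members.values())
    return _finalize(partition.level, t, clusters, ambiguous=flagged)


def _reference_name(record) -> str:
    """Display name of a named cultured record: binomial or genus + clade."""
    if record.species:
        return f"{record.genus} {record.species}"
    if record.clade:
        return f"{record.genus} clade {record.clade}"
    return ""


def name_otus(
    species_partition: OtuPartition,
    genus_partition: OtuPartition,
    dataset,
    anchor_id: str | None = None,
    family_ids: set[str] | None = None,
) -> dict[str, str]:
    """Assign display names to species-level OTUs.

    Naming precedence per OTU:

    1. Contains named cultured references of exactly one species -> that
       species name; several species -> a concatenated representative name.
    2. Shares its species-OTU with the family anchor strain (e.g. the
       Antarctic Kareniaceae culture RS24) -> the anchor's strain id.
    3. No reference at the species level but genus-level co-membership with
       named references -> the genus name; with the anchor -> "Kareniaceae
       <anchor>"; with unnamed family members (``family_ids``) ->
       ``Kar-fam`` labels.
    4. Otherwise sequential environmental-barcode labels ``EB<g>-<s>``
       where the genus number enumerates genus-OTUs and the species number
       enumerates species-OTUs within them, both in deterministic sorted
       order.
    """
    family_ids = family_ids or set()
    by_id = {r.record_id: r for r in dataset.records}
    anchor_strain = ""
    if anchor_id is not None and anchor_id in by_id:
        anchor_strain = by_id[anchor_id].strain_id or anchor_id

    def named_refs(ids):
        out = []
        for rid in ids:
            r = by_id.get(rid)
            if r is not None and r.source_class == "cultured" and r.is_named:
                out.append(_reference_name(r))
        return sorted(set(n for n in out if n))

    names: dict[str, str] = {}
    unresolved: list[str] = []  # species otu ids needing genus-level or EB names
    for otu_id, ids in species_partition.otu_members.items():
        refs = named_refs(ids)
        if len(refs) == 1:
            names[otu_id] = refs[0]
        elif refs:
            names[otu_id] = "/".join(refs)
        elif anchor_id is not None and anchor_id in ids:
            names[otu_id] = anchor_strain
        else:
            unresolved.append(otu_id)

    # genus-OTU of a species-OTU: taken from its smallest member id
    def genus_otu_of(species_otu: str) -> str:
        rep = species_partition.otu_members[species_otu][0]
        return genus_partition.assignments[rep]

    genus_names: dict[str, str] = {}
    genus_has_anchor: dict[str, bool] = {}
    genus_has_family: dict[str, bool] = {}
    for gid, ids in genus_partition.otu_members.items():
        genera = sorted(
            {
                by_id[rid].genus
                for rid in ids
                if rid in by_id
                and by_id[rid].source_class == "cultured"
                and by_id[rid].is_named
            }
        )
        genus_names[gid] = "/".join(genera)
        genus_has_anchor[gid] = anchor_id in ids if anchor_id else False
        genus_has_family[gid] = bool(set(ids) & family_ids)

    # EB / Kar-fam numbering: genus-OTUs hosting unresolved species OTUs,
    # ordered by smallest member id
    hosts: dict[str, list[str]] = {}
    for otu_id in unresolved:
        hosts.setdefault(genus_otu_of(otu_id), []).append(otu_id)
    ordered_hosts = sorted(hosts, key=lambda gid: genus_partition.otu_members[gid][0])
    eb_num = 0
    kar_num = 0
    for gid in ordered_hosts:
        sotus = sorted(hosts[gid], key=lambda o: species_partition.otu_members[o][0])
        if genus_names[gid]:
            for otu_id in sotus:
                names[otu_id] = f"{genus_names[gid]} sp."
        elif genus_has_anchor[gid]:
            for otu_id in sotus:
                names[otu_id] = f"Kareniaceae {anchor_strain}"
        elif genus_has_family[gid]:
            kar_num += 1
            for s, otu_id in enumerate(sotus, start=1):
                names[otu_id] = f"Kar-fam {kar_num}-{s}"
        else:
            eb_num += 1
            for s, otu_id in enumerate(sotus, start=1):
                names[otu_id] = f"EB{eb_num}-{s}"
    return names


def partition_frame(
    partition: OtuPartition,
    names: dict[str, str] | None = None,
    borderline: set[str] | None = None,
):
    """Long-form table of the partition: one row per record."""
    import pandas as pd

    names = names or {}
    borderline = borderline or set()
    rows = []
    for otu_id, ids in partition.otu_members.items():
        for rid in ids:
            rows.append(
                {
                    "record_id": rid,
                    "level": partition.level,
                    "threshold": partition.threshold,
                    "otu_id": otu_id,
                    "otu_name": names.get(otu_id, ""),
                    "ambiguous_flag": rid in partition.ambiguous,
                    "borderline_flag": rid in borderline,
                }
            )
    return pd.DataFrame(rows).sort_values("record_id").reset_index(drop=True)
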