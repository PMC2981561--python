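"""Complete-linkage OTU clustering: oracles, invariants, determinism."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from barcotu.cluster import (
    cluster_threshold,
    name_otus,
    resolve_ambiguous,
    validate_partition,
)
from barcotu.distance import DistanceMatrix
from barcotu.io import BarcodeDataset, BarcodeRecord


def dm(ids, d):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(list(ids), d, np.zeros_like(d, dtype=int))


def random_matrix(rng, n, scale=3.0):
    """Random symmetric matrix with continuous (tie-free) entries."""
    d = rng.uniform(0.05, scale, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


def as_sets(partition):
    return {frozenset(m) for m in partition.otu_members.values()}


def test_block_oracle_planted_clusters():
    # three blocks with intra <= 0.2 and inter >= 1.0: exact recovery
    rng = np.random.default_rng(0)
    sizes = [4, 3, 5]
    n = sum(sizes)
    d = np.full((n, n), 0.0)
    start = np.cumsum([0] + sizes)
    labels = np.concatenate([[k] * s for k, s in enumerate(sizes)])
    for i in range(n):
        for j in range(i + 1, n):
            v = rng.uniform(0.01, 0.2) if labels[i] == labels[j] else rng.uniform(1.0, 3.0)
            d[i, j] = d[j, i] = v
    ids = [f"r{k:02d}" for k in range(n)]
    part = cluster_threshold(dm(ids, d), threshold=0.24)
    expect = {
        frozenset(ids[start[k] : start[k + 1]]) for k in range(len(sizes))
    }
    assert as_sets(part) == expect
    validate_partition(part, dm(ids, d))


@given(st.integers(0, 2**32 - 1), st.integers(5, 20))
def test_matches_scipy_complete_linkage_cut(seed, n):
    rng = np.random.default_rng(seed)
    d = random_matrix(rng, n)
    ids = [f"r{k:02d}" for k in range(n)]
    t = float(rng.uniform(0.2, 2.5))
    part = cluster_threshold(dm(ids, d), threshold=t)
    Z = linkage(squareform(d, checks=False), method="complete")
    flat = fcluster(Z, t=t, criterion="distance")
    expect = {}
    for rid, c in zip(ids, flat):
        expect.setdefault(c, set()).add(rid)
    assert as_sets(part) == {frozenset(v) for v in expect.values()}


@given(st.integers(0, 2**32 - 1))
def test_complete_linkage_invariant_holds(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 25))
    d = random_matrix(rng, n)
    ids = [f"r{k:02d}" for k in range(n)]
    m = dm(ids, d)
    t = float(rng.uniform(0.1, 3.0))
    part = cluster_threshold(m, threshold=t)
    validate_partition(part, m)  # max intra-OTU PWD <= t


@given(st.integers(0, 2**32 - 1))
def test_threshold_monotonicity_refinement(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 20))
    d = random_matrix(rng, n)
    ids = [f"r{k:02d}" for k in range(n)]
    m = dm(ids, d)
    t1, t2 = sorted(rng.uniform(0.1, 3.0, size=2))
    fine = cluster_threshold(m, threshold=float(t1))
    coarse = cluster_threshold(m, threshold=float(t2))
    # every fine cluster is contained in exactly one coarse cluster
    for members in fine.otu_members.values():
        hosts = {coarse.assignments[r] for r in members}
        assert len(hosts) == 1
    assert fine.n_otus >= coarse.n_otus


def test_threshold_is_inclusive_at_boundary():
    ids = ["a", "b"]
    d = [[0.0, 0.24], [0.24, 0.0]]
    assert cluster_threshold(dm(ids, d), 0.24).n_otus == 1
    d2 = [[0.0, 0.2401], [0.2401, 0.0]]
    assert cluster_threshold(dm(ids, d2), 0.24).n_otus == 2


def test_permutation_invariance():
    rng = np.random.default_rng(5)
    n = 12
    d = random_matrix(rng, n)
    ids = [f"r{k:02d}" for k in range(n)]
    part1 = cluster_threshold(dm(ids, d), 1.0)
    perm = rng.permutation(n)
    part2 = cluster_threshold(dm([ids[p] for p in perm], d[np.ix_(perm, perm)]), 1.0)
    assert as_sets(part1) == as_sets(part2)
    assert part1.otu_members == part2.otu_members  # ids too, not just sets


def test_tie_break_prefers_smallest_member_id():
    # a-b and c-d both at distance 1; everything else far; both merges happen,
    # and otu ids enumerate clusters by smallest member
    ids = ["c", "d", "a", "b"]
    d = np.array(
        [
            [0.0, 1.0, 9.0, 9.0],
            [1.0, 0.0, 9.0, 9.0],
            [9.0, 9.0, 0.0, 1.0],
            [9.0, 9.0, 1.0, 0.0],
        ]
    )
    part = cluster_threshold(dm(ids, d), 1.0)
    assert part.otu_members["SOTU0001"] == ["a", "b"]
    assert part.otu_members["SOTU0002"] == ["c", "d"]


def test_edge_cases_empty_single():
    assert cluster_threshold(dm([], np.zeros((0, 0))), 1.0).n_otus == 0
    single = cluster_threshold(dm(["x"], np.zeros((1, 1))), 1.0)
    assert single.otu_members == {"SOTU0001": ["x"]}


def test_rejects_nonfinite_matrix():
    d = np.array([[0.0, np.nan], [np.nan, 0.0]])
    with pytest.raises(ValueError):
        cluster_threshold(dm(["a", "b"], d), 1.0)


def test_resolve_ambiguous_splits_conflicted_record():
    # chain a -(1)- b -(1)- c with a-c = 2 and threshold 1: complete linkage
    # groups {a,b} + {c}; b is within threshold of c (another OTU) and c of b
    ids = ["a", "b", "c"]
    d = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
    m = dm(ids, d)
    part = cluster_threshold(m, 1.0)
    assert as_sets(part) == {frozenset({"a", "b"}), frozenset({"c"})}
    resolved = resolve_ambiguous(part, m)
    assert resolved.ambiguous == {"b", "c"}
    assert as_sets(resolved) == {frozenset({"a"}), frozenset({"b", "c"})}
    validate_partition(resolved, m)


def test_resolve_ambiguous_no_op_on_clean_partition():
    ids = ["a", "b", "c", "d"]
    d = np.array(
        [
            [0.0, 0.1, 5.0, 5.0],
            [0.1, 0.0, 5.0, 5.0],
            [5.0, 5.0, 0.0, 0.1],
            [5.0, 5.0, 0.1, 0.0],
        ]
    )
    m = dm(ids, d)
    part = cluster_threshold(m, 1.0)
    resolved = resolve_ambiguous(part, m)
    assert resolved.ambiguous == set()
    assert as_sets(resolved) == as_sets(part)


def _naming_setup():
    records = [
        BarcodeRecord("ref_kb", "A" * 120, genus="Karenia", species="brevis"),
        BarcodeRecord("ref_km", "C" * 120, genus="Karenia", species="mikimotoi"),
        BarcodeRecord("anchor", "G" * 120, strain_id="RS24"),
        BarcodeRecord("env1", "T" * 120, source_class="environmental"),
        BarcodeRecord("env2", "T" * 60 + "A" * 60, source_class="environmental"),
        BarcodeRecord("env3", "T" * 30 + "G" * 90, source_class="environmental"),
    ]
    return BarcodeDataset(records)


def _partition_from(level, clusters):
    from barcotu.cluster import _finalize

    return _finalize(level, 0.0, clusters)


def test_name_otus_precedence():
    ds = _naming_setup()
    species = _partition_from(
        "species",
        [["ref_kb"], ["ref_km"], ["anchor"], ["env1"], ["env2"], ["env3"]],
    )
    genus = _partition_from(
        "genus",
        [["ref_kb", "ref_km", "env1"], ["anchor", "env2"], ["env3"]],
    )
    names = name_otus(species, genus, ds, anchor_id="anchor", family_ids={"anchor"})
    by_member = {
        species.otu_members[o][0]: n for o, n in names.items()
    }
    assert by_member["ref_kb"] == "Karenia brevis"
    assert by_member["ref_km"] == "Karenia mikimotoi"
    assert by_member["anchor"] == "RS24"
    assert by_member["env1"] == "Karenia sp."          # genus-level reference link
    assert by_member["env2"] == "Kareniaceae RS24"      # genus OTU shared with anchor
    assert by_member["env3"].startswith("EB")           # no reference at all


def test_name_otus_concatenates_shared_species():
    ds = BarcodeDataset(
        [
            BarcodeRecord("r1", "A" * 120, genus="Karenia", species="brevis"),
            BarcodeRecord("r2", "A" * 120, genus="Karenia", species="mikimotoi"),
        ]
    )
    species = _partition_from("species", [["r1", "r2"]])
    genus = _partition_from("genus", [["r1", "r2"]])
    names = name_otus(species, genus, ds)
    assert names["SOTU0001"] == "Karenia brevis/Karenia mikimotoi"
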