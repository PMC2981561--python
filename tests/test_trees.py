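"""Neighbor joining and principal coordinates: oracles and cross-checks."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from barcotu.distance import DistanceMatrix
from barcotu.trees import nj_tree, pcoa, plot_pcoa


def dm(ids, d):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(list(ids), d, np.zeros_like(d, dtype=int))


def random_additive_matrix(rng, n_leaves):
    """Distance matrix of a random binary tree with branch lengths >= 0.3.

    Clusters are joined in random order; cross-cluster leaf distances take
    the two new branch lengths, which keeps the metric exactly additive.
    """
    ids = [f"t{k:02d}" for k in range(n_leaves)]
    # each cluster: list of (leaf, distance to cluster root)
    clusters = [[(i, 0.0)] for i in ids]
    d = {}
    while len(clusters) > 2:
        a, b = sorted(rng.choice(len(clusters), size=2, replace=False))
        cb, ca = clusters.pop(b), clusters.pop(a)
        la, lb = rng.uniform(0.3, 2.0, size=2)
        for leaf_a, da in ca:
            for leaf_b, db in cb:
                d[frozenset((leaf_a, leaf_b))] = da + la + db + lb
        clusters.append([(l, x + la) for l, x in ca] + [(l, x + lb) for l, x in cb])
    edge = rng.uniform(0.3, 2.0)
    for leaf_a, da in clusters[0]:
        for leaf_b, db in clusters[1]:
            d[frozenset((leaf_a, leaf_b))] = da + db + edge
    mat = np.zeros((n_leaves, n_leaves))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i != j:
                mat[i, j] = d[frozenset((a, b))]
    return ids, mat


def test_three_taxon_closed_form():
    ids = ["a", "b", "c"]
    d = [[0, 2, 3], [2, 0, 4], [3, 4, 0]]
    tree = nj_tree(dm(ids, d))
    lengths = {child.name: l for child, l in tree.root.children}
    assert lengths == {"a": pytest.approx(0.5), "b": pytest.approx(1.5),
                       "c": pytest.approx(2.5)}
    leaves, paths = tree.path_lengths()
    got = {frozenset((leaves[i], leaves[j])): paths[i, j]
           for i in range(3) for j in range(i + 1, 3)}
    assert got[frozenset(("a", "b"))] == pytest.approx(2.0)
    assert got[frozenset(("a", "c"))] == pytest.approx(3.0)
    assert got[frozenset(("b", "c"))] == pytest.approx(4.0)


@given(st.integers(0, 2**32 - 1), st.integers(4, 8))
def test_additive_matrices_recovered_exactly(seed, n_leaves):
    rng = np.random.default_rng(seed)
    ids, mat = random_additive_matrix(rng, n_leaves)
    tree = nj_tree(dm(ids, mat))
    leaves, paths = tree.path_lengths()
    order = [leaves.index(i) for i in ids]
    assert np.allclose(paths[np.ix_(order, order)], mat, atol=1e-9)


def collect_lengths(node, out):
    for child, length in node.children:
        out.append(length)
        collect_lengths(child, out)
    return out


@given(st.integers(0, 2**32 - 1))
def test_branch_lengths_never_negative(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 12))
    d = rng.uniform(0.5, 5.0, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    tree = nj_tree(dm([f"t{k:02d}" for k in range(n)], d))
    assert min(collect_lengths(tree.root, [])) >= 0.0


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_topology_matches_skbio_nj(seed):
    import dendropy
    import skbio
    from dendropy.calculate import treecompare

    rng = np.random.default_rng(seed)
    n = 10
    d = rng.uniform(1.0, 8.0, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    ids = [f"t{k:02d}" for k in range(n)]
    ours = nj_tree(dm(ids, d)).to_newick()
    theirs = str(skbio.tree.nj(skbio.DistanceMatrix(d, ids)))
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=ours, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=theirs, schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    assert treecompare.symmetric_difference(t1, t2) == 0


def test_input_order_invariance_of_path_lengths():
    rng = np.random.default_rng(11)
    ids, mat = random_additive_matrix(rng, 7)
    perm = rng.permutation(len(ids))
    t1 = nj_tree(dm(ids, mat))
    t2 = nj_tree(dm([ids[p] for p in perm], mat[np.ix_(perm, perm)]))
    l1, p1 = t1.path_lengths()
    l2, p2 = t2.path_lengths()
    k1 = {i: k for k, i in enumerate(l1)}
    k2 = {i: k for k, i in enumerate(l2)}
    for a in ids:
        for b in ids:
            assert p1[k1[a], k1[b]] == pytest.approx(p2[k2[a], k2[b]], abs=1e-9)


def test_two_leaf_edge_and_too_small():
    tree = nj_tree(dm(["a", "b"], [[0.0, 3.0], [3.0, 0.0]]))
    _, paths = tree.path_lengths()
    assert paths[0, 1] == pytest.approx(3.0)
    with pytest.raises(ValueError):
        nj_tree(dm(["a"], [[0.0]]))


def test_newick_quotes_awkward_names():
    ids = ["plain", "needs quoting"]
    nwk = nj_tree(dm(ids, [[0.0, 1.0], [1.0, 0.0]])).to_newick()
    assert "'needs quoting'" in nwk
    assert nwk.endswith(";")


# ---------------------------------------------------------------- PCoA


def euclidean_dm(points, ids=None):
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return dm(ids or [f"p{k:02d}" for k in range(n)], d)


def test_pcoa_recovers_2d_configuration():
    pts = np.array([[0, 0], [3, 0], [3, 4], [0, 4], [1.5, 2.0]])
    res = pcoa(euclidean_dm(pts))
    assert res.coordinates.shape[1] == 2
    assert res.n_negative_dropped == 0
    # recovered up to rigid motion: the embedded distances match exactly
    emb = euclidean_dm(res.coordinates).d
    assert np.allclose(emb, euclidean_dm(pts).d, atol=1e-8)


def test_pcoa_recovers_3d_configuration():
    rng = np.random.default_rng(2)
    pts = rng.normal(size=(9, 3))
    res = pcoa(euclidean_dm(pts))
    assert res.coordinates.shape[1] == 3
    emb = euclidean_dm(res.coordinates).d
    assert np.allclose(emb, euclidean_dm(pts).d, atol=1e-8)
    # eigenvalues descending, variance percentages sum to 100
    assert np.all(np.diff(res.eigenvalues) <= 1e-12)
    assert res.pct_variance.sum() == pytest.approx(100.0)


def test_pcoa_matches_skbio():
    from skbio.stats.ordination import pcoa as sk_pcoa
    import skbio

    rng = np.random.default_rng(3)
    pts = rng.normal(size=(8, 3))
    m = euclidean_dm(pts)
    ours = pcoa(m)
    theirs = sk_pcoa(skbio.DistanceMatrix(m.d, m.ids), method="eigh")
    sk_eig = np.asarray(theirs.eigvals)
    assert np.allclose(ours.eigenvalues, sk_eig[: len(ours.eigenvalues)], atol=1e-8)
    sk_coords = np.asarray(theirs.samples)[:, : ours.coordinates.shape[1]]
    # axes agree up to sign
    for k in range(ours.coordinates.shape[1]):
        col, ref = ours.coordinates[:, k], sk_coords[:, k]
        assert np.allclose(col, ref, atol=1e-6) or np.allclose(col, -ref, atol=1e-6)


def test_pcoa_non_euclidean_drops_negative_axes():
    rng = np.random.default_rng(4)
    d = rng.uniform(0.5, 3.0, size=(7, 7))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    res = pcoa(dm([f"p{k}" for k in range(7)], d))
    assert res.n_negative_dropped > 0
    assert np.all(res.eigenvalues > 0)


def test_pcoa_sd_standardization_rescales_only():
    pts = np.array([[0, 0], [3, 0], [3, 4], [0, 4]], dtype=float)
    m = euclidean_dm(pts)
    raw = pcoa(m)
    std = pcoa(m, standardize="sd")
    off = m.d[~np.eye(4, dtype=bool)]
    ratio = off.std()
    assert np.allclose(np.abs(std.coordinates) * ratio, np.abs(raw.coordinates), atol=1e-8)
    with pytest.raises(ValueError):
        pcoa(m, standardize="zscore")


def test_pcoa_all_zero_matrix():
    res = pcoa(dm(["a", "b", "c"], np.zeros((3, 3))))
    assert np.all(res.coordinates == 0)
    assert res.n_negative_dropped == 0


def test_plot_pcoa_writes_figure(tmp_path):
    pts = np.array([[0, 0], [3, 0], [3, 4], [0, 4], [1, 1]], dtype=float)
    res = pcoa(euclidean_dm(pts))
    out = tmp_path / "pcoa.png"
    plot_pcoa(res, out, color_labels={"p00": "groupA"})
    assert out.stat().st_size > 0
    flat = pcoa(dm(["a", "b"], [[0.0, 1.0], [1.0, 0.0]]))
    with pytest.raises(ValueError):
        plot_pcoa(flat, tmp_path / "nope.png")
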