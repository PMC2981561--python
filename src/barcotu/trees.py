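"""Neighbor-joining clustergrams and principal coordinates analysis.

The NJ tree built from uncorrected distances is used here as a clustering
visualisation (a clustergram), not as a phylogeny: branch lengths are in
percent PWD units and the tree is emitted unrooted.

PCoA embeds the (optionally standardized, then squared) distance matrix via
Gower double-centering and an eigendecomposition; only axes with positive
eigenvalues are reported, and p-distance matrices that are not Euclidean
simply drop their negative-eigenvalue axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .distance import DistanceMatrix

logger = logging.getLogger("barcotu")


@dataclass
class NjNode:
    """A node of the clustergram; leaves carry a name, internals children."""

    name: str = ""
    children: list[tuple["NjNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class NjTree:
    """Unrooted NJ tree over record ids with branch lengths in percent."""

    root: NjNode  # internal node of degree 3 (or a 2-leaf edge)
    leaf_names: list[str]

    def to_newick(self) -> str:
        def fmt_name(name: str) -> str:
            if any(c in name for c in " ()[]:;,'"):
                return "'" + name.replace("'", "''") + "'"
            return name

        # iterative post-order walk: deep unbalanced join orders would
        # overflow the recursion limit on survey-sized trees
        rendered: dict[int, str] = {}
        stack: list[tuple[NjNode, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if node.is_leaf:
                rendered[id(node)] = fmt_name(node.name)
            elif not expanded:
                stack.append((node, True))
                for child, _ in node.children:
                    stack.append((child, False))
            else:
                inner = ",".join(
                    f"{rendered.pop(id(child))}:{length:.6f}"
                    for child, length in node.children
                )
                rendered[id(node)] = f"({inner})"
        return rendered[id(self.root)] + ";"

    def path_lengths(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf path length matrix (sums of branch lengths)."""
        # collect distances from every node to all leaves below/around it by
        # a double traversal over the (arbitrary rooted) structure
        leaves = self.leaf_names
        index = {name: i for i, name in enumerate(leaves)}
        n = len(leaves)
        dist = np.zeros((n, n))

        def below(node: NjNode) -> list[tuple[str, float]]:
            if node.is_leaf:
                return [(node.name, 0.0)]
            out = []
            groups = []
            for child, length in node.children:
                sub = [(name, d + length) for name, d in below(child)]
                groups.append(sub)
                out.extend(sub)
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for na, da in groups[gi]:
                        for nb, db in groups[gj]:
                            dist[index[na], index[nb]] = da + db
                            dist[index[nb], index[na]] = da + db
            return out

        below(self.root)
        return leaves, dist


def nj_tree(matrix: DistanceMatrix) -> NjTree:
    """Saitou–Nei neighbor joining with the Studier–Keppler criterion.

    At each step the pair minimising ``Q(i,j) = (n-2) d(i,j) - r(i) - r(j)``
    is joined; ties are broken by the lexicographically smallest pair of
    cluster labels (each cluster labelled by its smallest leaf id).
    Negative branch lengths are clamped to zero with the deficit moved to
    the sibling branch so the joined pair's path length is preserved.  On
    additive matrices the leaf-to-leaf path lengths reproduce the input
    exactly.
    """
    labels = list(matrix.ids)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two records")
    nodes: list[NjNode] = [NjNode(name=name) for name in labels]
    min_leaf = list(labels)

    if n == 2:
        logger.warning("fewer than 3 records: emitting a degenerate 2-leaf edge")
        half = matrix.d[0, 1] / 2
        root = NjNode(children=[(nodes[0], half), (nodes[1], half)])
        return NjTree(root, labels)

    # preallocate for all internal nodes created during agglomeration
    total = 2 * n - 2
    D = np.zeros((total, total))
    D[:n, :n] = matrix.d

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        # floating-point subtraction order differs between the two triangles,
        # so Q is not bitwise symmetric; search the upper triangle only
        Q[np.tril_indices(m)] = np.inf
        qmin = Q.min()
        best = None
        for a, b in zip(*np.nonzero(Q == qmin)):
            if a >= b:
                continue
            key = tuple(sorted((min_leaf[active[a]], min_leaf[active[b]])))
            if best is None or key < best[0]:
                best = (key, int(a), int(b))
        _, a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = dij / 2 + (r[a] - r[b]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            lj, li = 0.0, dij

        parent = NjNode(children=[(nodes[i], li), (nodes[j], lj)])
        k = len(nodes)
        newd = 0.5 * (D[i, :] + D[j, :] - dij)
        D[k, :] = newd
        D[:, k] = newd
        D[k, k] = 0.0
        nodes.append(parent)
        min_leaf.append(min(min_leaf[i], min_leaf[j]))
        active = [x for x in active if x not in (i, j)] + [k]

    # final 3-node star with closed-form branch lengths
    i, j, k = active
    dij, dik, djk = D[i, j], D[i, k], D[j, k]
    li = (dij + dik - djk) / 2
    lj = (dij + djk - dik) / 2
    lk = (dik + djk - dij) / 2
    lengths = [max(x, 0.0) for x in (li, lj, lk)]
    root = NjNode(
        children=[(nodes[i], lengths[0]), (nodes[j], lengths[1]), (nodes[k], lengths[2])]
    )
    return NjTree(root, labels)


@dataclass
class PcoaResult:
    ids: list[str]
    coordinates: np.ndarray  # records x axes, positive-eigenvalue axes only
    eigenvalues: np.ndarray  # positive, descending
    pct_variance: np.ndarray
    n_negative_dropped: int = 0

    def frame(self):
        import pandas as pd

        cols = [f"axis_{k + 1}" for k in range(self.coordinates.shape[1])]
        out = pd.DataFrame(self.coordinates, columns=cols)
        out.insert(0, "record_id", self.ids)
        return out


def pcoa(
    matrix: DistanceMatrix,
    standardize: str = "none",
    eig_tol: float = 1e-9,
) -> PcoaResult:
    """Principal coordinates of a distance matrix.

    With ``standardize="sd"`` distances are first divided by the standard
    deviation of all off-diagonal distances (scale-invariant cluster
    membership either way).  The (squared) distances are Gower
    double-centered, eigendecomposed, and coordinates scaled by the square
    root of each positive eigenvalue.  Negative-eigenvalue axes are dropped
    (counted in ``n_negative_dropped``), not corrected.
    """
    if standardize not in ("none", "sd"):
        raise ValueError("standardize must be 'none' or 'sd'")
    d = matrix.d.astype(float).copy()
    n = d.shape[0]
    if standardize == "sd":
        off = d[~np.eye(n, dtype=bool)]
        sd = off.std()
        if sd > 0:
            d = d / sd
    if not d.any():
        logger.warning("all-zero distance matrix: PCoA coordinates are zero")
        return PcoaResult(list(matrix.ids), np.zeros((n, 1)), np.zeros(1), np.zeros(1))

    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    b = a - row - col + a.mean()
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = max(abs(eigvals[0]), 1.0)
    positive = eigvals > eig_tol * scale
    n_neg = int((eigvals < -eig_tol * scale).sum())
    lam = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(lam)[None, :]
    pct = 100.0 * lam / lam.sum() if lam.size else lam
    return PcoaResult(list(matrix.ids), coords, lam, pct, n_negative_dropped=n_neg)


def plot_pcoa(result: PcoaResult, path, color_labels: dict[str, str] | None = None) -> None:
    """Scatter of the first two principal coordinates, coloured by label."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if result.coordinates.shape[1] < 2:
        raise ValueError("need at least two positive axes to plot")
    x, y = result.coordinates[:, 0], result.coordinates[:, 1]
    labels = [
        (color_labels or {}).get(rid, "unlabelled") for rid in result.ids
    ]
    fig, ax = plt.subplots(figsize=(7, 6))
    for lab in sorted(set(labels)):
        mask = np.array([l == lab for l in labels])
        ax.scatter(x[mask], y[mask], s=12, label=lab, alpha=0.7)
    ax.set_xlabel(f"PCo1 ({result.pct_variance[0]:.1f}%)")
    ax.set_ylabel(f"PCo2 ({result.pct_variance[1]:.1f}%)")
    ax.legend(fontsize=7, markerscale=1.5, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
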