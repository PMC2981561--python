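"""Uncorrected pairwise distances (p-distances) with pairwise deletion.

Distances are carried in percent throughout, matching how they are reported
in barcoding practice: the distance between two aligned barcodes is
``100 * mismatches / comparable sites`` where a site is *comparable* only
when both characters are unambiguous bases (A, C, G or T).  Ambiguity codes
and gaps are removed pairwise, from the numerator and the denominator
alike, so a heterozygous position neither matches nor mismatches.
Transitions and transversions are weighted equally.

The distance is not guaranteed to satisfy the triangle inequality once
pairwise deletion removes different site sets for different pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import BarcodeDataset

_BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(_BASES)}


class InsufficientOverlapError(ValueError):
    """Raised when a pair of sequences shares fewer comparable sites than required."""


@dataclass
class DistanceMatrix:
    """Symmetric matrix of percent p-distances with comparable-site counts."""

    ids: list[str]
    d: np.ndarray       # percent, zero diagonal
    n_sites: np.ndarray  # comparable sites per pair

    def __post_init__(self) -> None:
        self._index = {rid: i for i, rid in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise ValueError("duplicate ids in distance matrix")

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, record_id: str) -> int:
        return self._index[record_id]

    def get(self, a: str, b: str) -> float:
        return float(self.d[self._index[a], self._index[b]])

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        idx = np.array([self._index[i] for i in ids])
        return DistanceMatrix(list(ids), self.d[np.ix_(idx, idx)], self.n_sites[np.ix_(idx, idx)])

    def to_long_frame(self):
        """Long-form table of all unordered pairs: id_a, id_b, pwd_percent, n_sites."""
        import pandas as pd

        rows = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append(
                    (self.ids[i], self.ids[j], float(self.d[i, j]), int(self.n_sites[i, j]))
                )
        return pd.DataFrame(rows, columns=["id_a", "id_b", "pwd_percent", "n_sites"])

    def write_phylip(self, path) -> None:
        """Write the matrix in square PHYLIP format."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, rid in enumerate(self.ids):
                vals = " ".join(f"{v:.6f}" for v in self.d[i])
                fh.write(f"{rid}  {vals}\n")

    @classmethod
    def read_phylip(cls, path) -> "DistanceMatrix":
        with open(path) as fh:
            n = int(fh.readline().split()[0])
            ids, rows = [], []
            for _ in range(n):
                parts = fh.readline().split()
                ids.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        d = np.asarray(rows, dtype=float)
        return cls(ids, d, np.zeros_like(d, dtype=int))


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to integer codes; anything outside ACGT becomes 4."""
    arr = np.full(len(seq), 4, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = code
    return arr


def p_distance(a: str, b: str, min_overlap: int = 100) -> tuple[float, int]:
    """Percent p-distance and comparable-site count between two sequences.

    Raises :class:`InsufficientOverlapError` when fewer than ``min_overlap``
    sites are comparable.
    """
    if len(a) != len(b):
        raise ValueError("sequences must be the same length")
    ca, cb = _encode(a), _encode(b)
    valid = (ca < 4) & (cb < 4)
    n = int(valid.sum())
    if n < min_overlap:
        raise InsufficientOverlapError(
            f"only {n} comparable sites; minimum is {min_overlap}"
        )
    mismatches = int(((ca != cb) & valid).sum())
    return 100.0 * mismatches / n, n


def distance_matrix(dataset: BarcodeDataset, min_overlap: int = 100) -> DistanceMatrix:
    """All-pairs percent p-distance matrix over a trimmed dataset.

    Implemented with per-base indicator matrix products so the full culture
    collection plus environmental survey (about a thousand records) is
    computed in a few matrix multiplications.  Any pair sharing fewer than
    ``min_overlap`` comparable sites raises, naming the offending pair.
    """
    if len(dataset) < 2:
        raise ValueError("need at least two records for a distance matrix")
    lengths = {len(r.sequence) for r in dataset.records}
    if len(lengths) != 1:
        raise ValueError("dataset must be trimmed to a common length first")

    codes = np.stack([_encode(r.sequence) for r in dataset.records])
    valid = codes < 4
    matches = np.zeros((len(dataset), len(dataset)))
    for code in range(4):
        ind = (codes == code).astype(np.float64)
        matches += ind @ ind.T
    n_sites = valid.astype(np.float64) @ valid.astype(np.float64).T
    n_sites_i = np.rint(n_sites).astype(np.int64)
    mism = np.rint(n_sites - matches).astype(np.int64)

    off_diag = ~np.eye(len(dataset), dtype=bool)
    low = (n_sites_i < min_overlap) & off_diag
    if low.any():
        i, j = np.argwhere(low)[0]
        raise InsufficientOverlapError(
            f"pair ({dataset.ids[i]}, {dataset.ids[j]}) shares only "
            f"{n_sites_i[i, j]} comparable sites; minimum is {min_overlap}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 100.0 * mism / n_sites_i
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(dataset.ids, d, n_sites_i)


def group_pwd_stats(
    matrix: DistanceMatrix, groups: dict[str, str]
) -> tuple[dict, dict]:
    """Within-group and between-group PWD summaries.

    ``groups`` maps record id -> group label; records absent from the map
    are ignored.  Returns ``(intra, inter)`` where ``intra[label]`` is a
    dict with ``mean``/``min``/``max``/``n_pairs`` over all unordered
    within-group pairs (labels with fewer than two members are omitted) and
    ``inter[(label_a, label_b)]`` the same over all between-group pairs.
    """
    members: dict[str, list[int]] = {}
    for rid, label in groups.items():
        if rid in matrix._index:
            members.setdefault(label, []).append(matrix.index(rid))

    def stats(values: np.ndarray) -> dict:
        return {
            "mean": float(values.mean()),
            "min": float(values.min()),
            "max": float(values.max()),
            "n_pairs": int(values.size),
        }

    intra = {}
    for label, idx in members.items():
        if len(idx) < 2:
            continue
        sub = matrix.d[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        intra[label] = stats(sub[iu])

    inter = {}
    labels = sorted(members)
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            block = matrix.d[np.ix_(members[la], members[lb])]
            inter[(la, lb)] = stats(block.ravel())
    return intra, inter
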