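"""Cut-off diagnostics from the named reference library.

The species-level cut-off is justified by comparing the distribution of
p-distances between conspecific strain isolates (intra-species) with that
between species of the same genus (inter-species), and by asking what
fraction of named strains would be correctly assignable at a candidate
cut-off.  A strain is *assignable at cut-off c* when its most distant
conspecific is within c and its closest heterospecific named strain is
beyond c — i.e. the cut-off separates it from everything but its own
species.

Some taxa are excluded from these calculations by default: *Alexandrium*
(COI too conserved to separate its species), *Protoceratium* and
*Lingulodinium* (genus-level failures), *Symbiodinium* (species definitions
do not apply; the genus is organised into clades), and all *Gymnodinium*
other than *G. catenatum* and *G. impudicum* (the rest of the genus is
paraphyletic).  Strains lacking species-level names never enter
calibration, although they remain in the rest of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distance import DistanceMatrix
from .io import BarcodeRecord

#: Genera fully excluded from assignability calculations.
DEFAULT_EXCLUDED_GENERA = frozenset(
    {"Alexandrium", "Protoceratium", "Lingulodinium", "Symbiodinium"}
)

#: Genera excluded except for a whitelist of species (paraphyly).
DEFAULT_SPECIES_WHITELIST = {"Gymnodinium": frozenset({"catenatum", "impudicum"})}

#: Genera whose inter-species divergence is an outlier regime and must not
#: inform the genus-level bound (deep internal splits / clade structure).
OUTLIER_GENERA = frozenset({"Prorocentrum", "Pyrocystis", "Symbiodinium"})

#: Default genus-level bound in percent and the cap on empirical bounds.
DEFAULT_GENUS_BOUND = 1.4
GENUS_BOUND_CAP = 5.9


@dataclass(frozen=True)
class TaxonExclusions:
    """Taxa removed from calibration: whole genera, or genera with a
    species whitelist that is kept."""

    genera: frozenset[str] = frozenset()
    species_whitelist: dict[str, frozenset[str]] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "TaxonExclusions":
        return cls(DEFAULT_EXCLUDED_GENERA, dict(DEFAULT_SPECIES_WHITELIST))

    @classmethod
    def none(cls) -> "TaxonExclusions":
        return cls()

    def excludes(self, record: BarcodeRecord) -> bool:
        if record.genus in self.genera:
            return True
        keep = self.species_whitelist.get(record.genus)
        if keep is not None and record.species not in keep:
            return True
        return False


@dataclass
class CalibrationSummary:
    """Intra/inter-species PWD distributions and assignability fractions."""

    intra_species_pwds: list[tuple[str, tuple[str, str], float]]
    inter_species_pwds: list[tuple[str, tuple[str, str], float]]
    assignable_fraction: dict[float, float]
    excluded_taxa: set[str]
    n_strains: int = 0

    def scatter_frame(self):
        """Long-form export of both distributions: group_type, label, pwd."""
        import pandas as pd

        rows = [
            ("intra_species", label, pwd)
            for label, _, pwd in self.intra_species_pwds
        ] + [
            ("inter_species", label, pwd)
            for label, _, pwd in self.inter_species_pwds
        ]
        return pd.DataFrame(rows, columns=["group_type", "label", "pwd_percent"])


def _species_label(r: BarcodeRecord) -> str:
    """Species-level label: the binomial, or genus + clade for clade-organised
    genera such as *Symbiodinium*."""
    if r.species:
        return f"{r.genus} {r.species}"
    if r.clade:
        return f"{r.genus} clade {r.clade}"
    return ""


def calibrate(
    matrix: DistanceMatrix,
    references: list[BarcodeRecord],
    exclusions: TaxonExclusions | None = None,
    cutoffs: tuple[float, ...] = (0.24,),
) -> CalibrationSummary:
    """Compute intra/inter-species PWD distributions and assignability.

    ``references`` are cultured records; only those with species-level
    labels participate.  ``exclusions`` removes taxa from the assignability
    statistic (numerator and denominator alike) and from the distributions.
    """
    if exclusions is None:
        exclusions = TaxonExclusions.none()
    named = [
        r
        for r in references
        if r.is_named and r.record_id in matrix._index and not exclusions.excludes(r)
    ]
    if not named:
        raise ValueError("no named reference strains after exclusions")

    labels = {r.record_id: _species_label(r) for r in named}
    genera = {r.record_id: r.genus for r in named}
    ids = [r.record_id for r in named]
    idx = np.array([matrix.index(i) for i in ids])
    sub = matrix.d[np.ix_(idx, idx)]

    intra, inter = [], []
    n = len(ids)
    any_conspecific = False
    for i in range(n):
        for j in range(i + 1, n):
            a, b = ids[i], ids[j]
            pwd = float(sub[i, j])
            if labels[a] == labels[b]:
                intra.append((labels[a], (a, b), pwd))
                any_conspecific = True
            elif genera[a] == genera[b]:
                inter.append((genera[a], (labels[a], labels[b]), pwd))
    if not any_conspecific:
        raise ValueError("no conspecific strain pairs; cannot calibrate")

    # assignability: per strain, max PWD to conspecifics and min PWD to
    # heterospecific named strains (any genus)
    lab_arr = np.array([labels[i] for i in ids])
    fractions: dict[float, float] = {}
    for c in cutoffs:
        n_assignable = 0
        for i in range(n):
            same = (lab_arr == lab_arr[i]) & (np.arange(n) != i)
            other = lab_arr != lab_arr[i]
            max_intra = float(sub[i, same].max()) if same.any() else 0.0
            min_inter = float(sub[i, other].min()) if other.any() else np.inf
            if max_intra <= c and min_inter > c:
                n_assignable += 1
        fractions[c] = n_assignable / n

    excluded_names = set(exclusions.genera)
    for genus, keep in exclusions.species_whitelist.items():
        excluded_names.add(f"{genus} (except {', '.join(sorted(keep))})")
    return CalibrationSummary(
        intra_species_pwds=intra,
        inter_species_pwds=inter,
        assignable_fraction=fractions,
        excluded_taxa=excluded_names,
        n_strains=n,
    )


def genus_bound_table(
    summary: CalibrationSummary,
    default: float = DEFAULT_GENUS_BOUND,
    cap: float = GENUS_BOUND_CAP,
    outliers: frozenset[str] = OUTLIER_GENERA,
) -> dict[str, float]:
    """Per-genus binning bound for environmental identification.

    The bound is the maximum observed inter-species PWD within the genus,
    capped at ``cap``; outlier genera (deep internal splits) and genera
    represented by fewer than two species fall back to the ``default``
    average lower genus range.
    """
    by_genus: dict[str, list[float]] = {}
    species_seen: dict[str, set[str]] = {}
    for genus, pair, pwd in summary.inter_species_pwds:
        by_genus.setdefault(genus, []).append(pwd)
        species_seen.setdefault(genus, set()).update(pair)
    bounds = {}
    for genus, pwds in by_genus.items():
        if genus in outliers or len(species_seen.get(genus, ())) < 2:
            bounds[genus] = default
        else:
            bounds[genus] = min(max(pwds), cap)
    return bounds
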