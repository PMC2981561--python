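"""Pseudogene screening and paralogue detection for COI barcodes.

Dinoflagellate mitochondrial genomes carry fragmented gene copies and use
RNA editing, so an amplified COI barcode can be a pseudogene (betrayed by
in-frame stop codons) or one of several divergent paralogous copies
(betrayed by elevated diversity among cloned amplicons of a single strain).

Pseudogene screen: a record fails when its translation contains a stop
codon, unless the stop sits at a known RNA-editing position (where the
transcript is repaired post-transcriptionally) or the identical stop is
shared by several strains of the same named species, which indicates a
genuine editing site rather than decay.  Codons containing ambiguity codes
translate to X and never count as stops.

Paralogue test: for a strain with cloned amplicons, the mean p-distance over
all clone/direct-sequence pairs is compared to the species-level cut-off
(0.24% by default).  Clean strains sit well below it (<= 0.2%); a strain
carrying divergent COI copies shows means several-fold higher.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .distance import DistanceMatrix, p_distance
from .io import BarcodeDataset, BarcodeRecord, stop_codons_for_table

logger = logging.getLogger("barcotu")


@dataclass
class QcConfig:
    """Configuration for the frame/paralogue screens.

    genetic_code_id
        NCBI translation table; defaults to 4 (mold/protozoan
        mitochondrial), the usual choice for dinoflagellate mitochondria.
    editing_sites
        0-based alignment positions (first nucleotide of the codon) exempt
        from stop-codon failure.  Ships empty; coordinates are organism
        specific and must be supplied.
    paralogue_pwd_threshold
        Percent PWD above which a clone-group mean flags a paralogue;
        defaults to the species OTU cut-off.
    """

    genetic_code_id: int = 4
    editing_sites: set[int] = field(default_factory=set)
    paralogue_pwd_threshold: float = 0.24

    def __post_init__(self) -> None:
        if self.paralogue_pwd_threshold <= 0:
            raise ValueError("paralogue_pwd_threshold must be positive")


@dataclass(frozen=True)
class PseudogeneVerdict:
    record_id: str
    passed: bool
    fail_position: int | None = None  # 0-based first nucleotide of the stop codon


@dataclass(frozen=True)
class ParalogueReport:
    strain_id: str
    n_clones: int
    mean_within_pwd: float
    max_within_pwd: float
    flagged: bool


def _stop_positions(sequence: str, frame_offset: int, stops: frozenset[str]) -> list[int]:
    out = []
    for i in range(frame_offset, len(sequence) - 2, 3):
        codon = sequence[i : i + 3]
        if set(codon) <= set("ACGT") and codon in stops:
            out.append(i)
    return out


def screen_pseudogenes(
    dataset: BarcodeDataset, cfg: QcConfig
) -> dict[str, PseudogeneVerdict]:
    """Per-record pass/fail verdicts for in-frame stop codons.

    The dataset must already be trimmed and framed.  Stops shared by at
    least two distinct strains of the same named species are treated as
    previously unreported editing sites: they are exempted for every record
    and logged.  Verdicts do not depend on record order.
    """
    stops = stop_codons_for_table(cfg.genetic_code_id)
    offset = dataset.frame_offset

    raw: dict[str, list[int]] = {
        r.record_id: _stop_positions(r.sequence, offset, stops) for r in dataset.records
    }

    # positions shared by >=2 strains of one named species are exempt
    shared: set[int] = set()
    by_species_pos: dict[tuple[str, int], set[str]] = {}
    for r in dataset.records:
        if not (r.binomial and r.strain_id):
            continue
        for pos in raw[r.record_id]:
            by_species_pos.setdefault((r.binomial, pos), set()).add(r.strain_id)
    for (binomial, pos), strains in sorted(by_species_pos.items()):
        if len(strains) >= 2:
            shared.add(pos)
            logger.info(
                "stop at position %d shared by %d strains of %s; "
                "treating as an RNA editing site",
                pos,
                len(strains),
                binomial,
            )

    exempt = set(cfg.editing_sites) | shared
    verdicts = {}
    for r in dataset.records:
        offending = [p for p in raw[r.record_id] if p not in exempt]
        if offending:
            verdicts[r.record_id] = PseudogeneVerdict(r.record_id, False, offending[0])
        else:
            verdicts[r.record_id] = PseudogeneVerdict(r.record_id, True)
    return verdicts


def paralogue_test(
    clone_group: list[BarcodeRecord],
    cfg: QcConfig,
    matrix: DistanceMatrix | None = None,
    min_overlap: int = 100,
) -> ParalogueReport:
    """Mean within-strain PWD over a clone group (clones + direct sequence).

    ``clone_group`` holds every cloned amplicon of one strain together with
    the directly sequenced barcode.  Distances are taken from ``matrix``
    when given, else computed pairwise.  The group is flagged when the mean
    over all unordered pairs exceeds ``cfg.paralogue_pwd_threshold``.
    """
    if len(clone_group) < 2:
        raise ValueError("paralogue test needs at least two sequences per strain")
    strains = {r.strain_id for r in clone_group if r.strain_id}
    if len(strains) > 1:
        raise ValueError(f"clone group mixes strains: {sorted(strains)}")
    strain_id = next(iter(strains)) if strains else clone_group[0].record_id

    vals = []
    for i, a in enumerate(clone_group):
        for b in clone_group[i + 1 :]:
            if matrix is not None:
                vals.append(matrix.get(a.record_id, b.record_id))
            else:
                vals.append(p_distance(a.sequence, b.sequence, min_overlap)[0])
    arr = np.asarray(vals)
    mean = float(arr.mean())
    return ParalogueReport(
        strain_id=strain_id,
        n_clones=len(clone_group),
        mean_within_pwd=mean,
        max_within_pwd=float(arr.max()),
        flagged=mean > cfg.paralogue_pwd_threshold,
    )


def paralogue_reports(
    dataset: BarcodeDataset, cfg: QcConfig, min_overlap: int = 100
) -> list[ParalogueReport]:
    """Run :func:`paralogue_test` for every strain with a clone set.

    A clone set is a strain's direct sequence plus all records whose
    ``clone_parent`` points at it (or that share its ``strain_id`` with
    source class ``clone``).
    """
    groups: dict[str, list[BarcodeRecord]] = {}
    by_id = {r.record_id: r for r in dataset.records}
    for r in dataset.records:
        if r.source_class == "clone":
            parent = by_id.get(r.clone_parent)
            key = parent.strain_id if parent is not None and parent.strain_id else r.strain_id
            groups.setdefault(key or r.clone_parent, []).append(r)
    reports = []
    for strain_id in sorted(groups):
        members = list(groups[strain_id])
        direct = [
            r
            for r in dataset.records
            if r.strain_id == strain_id and r.source_class != "clone"
        ]
        members.extend(direct)
        if len(members) >= 2:
            reports.append(paralogue_test(members, cfg, min_overlap=min_overlap))
    return reports
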