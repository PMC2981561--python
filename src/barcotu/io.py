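"""Reading, writing and assembly of COI barcode datasets.

A *barcode dataset* couples a set of same-locus mitochondrial COI amplicon
sequences with per-record provenance: taxonomy as deposited by the culture
collection (genus, species, *Symbiodinium* clade), the source class
(cultured strain, environmental clone, single cell, or clone-library
sequence), and the sampling context (site, depth, season) used for the
environmental surveys.

The COI barcode region is amplified with fixed nested primers and is treated
here as gap-free and in frame: no internal alignment is performed, only
terminal trimming to the longest shared window plus detection of the common
reading frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("barcotu")

#: IUPAC nucleotide one-letter codes plus the gap character.
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN-")

#: Columns of the metadata table, in canonical order.
METADATA_COLUMNS = [
    "record_id",
    "genus",
    "species",
    "clade",
    "strain_id",
    "source_class",
    "clone_parent",
    "site",
    "depth_m",
    "season",
    "accession",
]

SOURCE_CLASSES = frozenset({"cultured", "environmental", "single_cell", "clone"})
SEASONS = frozenset({"summer", "winter", "unknown"})


class BarcodeIOError(ValueError):
    """Raised on malformed FASTA/metadata input."""


@dataclass(frozen=True)
class BarcodeRecord:
    """One barcode sequence with its taxonomy and provenance."""

    record_id: str
    sequence: str
    source_class: str = "cultured"
    genus: str = ""
    species: str = ""
    clade: str = ""
    strain_id: str = ""
    clone_parent: str = ""
    site: str = ""
    depth_m: float | None = None
    season: str = "unknown"
    accession: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise BarcodeIOError(f"record {self.record_id!r} has an empty sequence")
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            raise BarcodeIOError(
                f"record {self.record_id!r} contains non-IUPAC characters: {sorted(bad)}"
            )
        if self.source_class not in SOURCE_CLASSES:
            raise BarcodeIOError(
                f"record {self.record_id!r}: unknown source_class {self.source_class!r}"
            )
        if self.season not in SEASONS:
            raise BarcodeIOError(
                f"record {self.record_id!r}: unknown season {self.season!r}"
            )
        if self.depth_m is not None and self.depth_m < 0:
            raise BarcodeIOError(f"record {self.record_id!r}: negative depth")

    @property
    def binomial(self) -> str:
        """``Genus species`` when both are present, else empty."""
        if self.genus and self.species:
            return f"{self.genus} {self.species}"
        return ""

    @property
    def is_named(self) -> bool:
        """True when the record carries a species-level (or clade) label."""
        return bool(self.genus and (self.species or self.clade))


@dataclass
class BarcodeDataset:
    """An ordered collection of barcode records over one locus.

    ``alignment_length`` is set once all sequences share a common trimmed
    window; ``frame_offset`` (0, 1 or 2) is the position of the first
    complete codon.  Translation starts at ``frame_offset``; a 3' tail that
    is not a whole codon is permitted.
    """

    records: list[BarcodeRecord]
    alignment_length: int | None = None
    frame_offset: int = 0

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise BarcodeIOError(f"duplicate record ids: {dupes}")
        known = set(ids)
        for r in self.records:
            if r.clone_parent and r.clone_parent not in known:
                raise BarcodeIOError(
                    f"record {r.record_id!r}: clone_parent {r.clone_parent!r} not in dataset"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.record_id for r in self.records]

    def get(self, record_id: str) -> BarcodeRecord:
        for r in self.records:
            if r.record_id == record_id:
                return r
        raise KeyError(record_id)

    def subset(self, ids: Iterable[str]) -> "BarcodeDataset":
        keep = set(ids)
        recs = [r for r in self.records if r.record_id in keep]
        # clone_parent links may now dangle; drop them rather than fail
        recs = [
            replace(r, clone_parent="") if r.clone_parent and r.clone_parent not in keep else r
            for r in recs
        ]
        return BarcodeDataset(recs, self.alignment_length, self.frame_offset)

    def metadata_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "record_id": r.record_id,
                    "genus": r.genus,
                    "species": r.species,
                    "clade": r.clade,
                    "strain_id": r.strain_id,
                    "source_class": r.source_class,
                    "clone_parent": r.clone_parent,
                    "site": r.site,
                    "depth_m": "" if r.depth_m is None else r.depth_m,
                    "season": r.season,
                    "accession": r.accession,
                }
            )
        return pd.DataFrame(rows, columns=METADATA_COLUMNS)


def _normalize_sequence(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_dataset(fasta_path: str | Path, metadata_path: str | Path) -> BarcodeDataset:
    """Read a FASTA file and its metadata TSV into a :class:`BarcodeDataset`.

    Records keep file order.  Sequences are upper-cased and RNA ``U`` is
    mapped to ``T``.  FASTA ids absent from the metadata table are retained
    with empty taxonomy fields and a logged warning; duplicate FASTA ids and
    empty files are hard errors.
    """
    fasta_path = Path(fasta_path)
    seqs = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not seqs:
        raise BarcodeIOError(f"no sequences found in {fasta_path}")
    ids = [s.id for s in seqs]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise BarcodeIOError(f"duplicate FASTA ids in {fasta_path}: {dupes}")

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
    if "record_id" not in meta.columns:
        raise BarcodeIOError(f"metadata table {metadata_path} lacks a record_id column")
    rows: Mapping[str, dict] = {row["record_id"]: dict(row) for _, row in meta.iterrows()}

    records = []
    for s in seqs:
        row = rows.get(s.id)
        if row is None:
            logger.warning("record %s has no metadata row; taxonomy left empty", s.id)
            row = {}
        depth = row.get("depth_m", "")
        records.append(
            BarcodeRecord(
                record_id=s.id,
                sequence=_normalize_sequence(str(s.seq)),
                source_class=row.get("source_class", "") or "cultured",
                genus=row.get("genus", ""),
                species=row.get("species", ""),
                clade=row.get("clade", ""),
                strain_id=row.get("strain_id", ""),
                clone_parent=row.get("clone_parent", ""),
                site=row.get("site", ""),
                depth_m=float(depth) if depth not in ("", None) else None,
                season=row.get("season", "") or "unknown",
                accession=row.get("accession", ""),
            )
        )
    return BarcodeDataset(records)


def write_dataset(
    dataset: BarcodeDataset,
    fasta_path: str | Path,
    metadata_path: str | Path,
    line_width: int = 70,
) -> None:
    """Write the dataset back out as FASTA plus the metadata TSV."""
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.record_id, description="") for r in dataset.records
    ]
    with open(fasta_path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(seqrecs)
    dataset.metadata_frame().to_csv(metadata_path, sep="\t", index=False)


def _count_stops(sequence: str, offset: int, stop_codons: frozenset[str]) -> int:
    n = 0
    for i in range(offset, len(sequence) - 2, 3):
        if sequence[i : i + 3] in stop_codons:
            n += 1
    return n


def stop_codons_for_table(genetic_code_id: int) -> frozenset[str]:
    """Stop codons of an NCBI translation table (default elsewhere: table 4)."""
    try:
        table = CodonTable.unambiguous_dna_by_id[genetic_code_id]
    except KeyError as exc:
        raise BarcodeIOError(f"unknown genetic code table id {genetic_code_id}") from exc
    return frozenset(table.stop_codons)


def trim_to_common_frame(
    dataset: BarcodeDataset,
    genetic_code_id: int = 4,
    min_window: int = 100,
) -> BarcodeDataset:
    """Trim all sequences to the longest shared window and detect the frame.

    Sequences are assumed to start at the same 5' position (fixed nested
    primers) and to vary only in 3' extent, so the shared window is simply a
    truncation to the shortest length.  The reading frame is then chosen, in
    {0, 1, 2}, to minimise the total number of in-frame stop codons over the
    named cultured records (over all records when none are named), since
    functional COI from healthy cultures should translate without
    interruption.
    """
    if not dataset.records:
        raise BarcodeIOError("cannot trim an empty dataset")
    window = min(len(r.sequence) for r in dataset.records)
    if window < min_window:
        raise BarcodeIOError(
            f"shared window of {window} sites is shorter than the required {min_window}"
        )
    trimmed = [replace(r, sequence=r.sequence[:window]) for r in dataset.records]

    stops = stop_codons_for_table(genetic_code_id)
    calib = [r for r in trimmed if r.source_class == "cultured" and r.is_named]
    if not calib:
        calib = trimmed
    totals = {
        off: sum(_count_stops(r.sequence, off, stops) for r in calib) for off in (0, 1, 2)
    }
    frame = min(totals, key=lambda off: (totals[off], off))
    return BarcodeDataset(trimmed, alignment_length=window, frame_offset=frame)


def dereplicate(
    dataset: BarcodeDataset, scope: str = "all"
) -> tuple[BarcodeDataset, dict[str, list[str]]]:
    """Collapse exactly identical sequences to one representative.

    Duplicate detection is exact string equality on the trimmed sequence.
    The representative is the member with the lexicographically smallest
    ``record_id``.  With ``scope="environmental_only"`` only records of
    source class ``environmental``, ``single_cell`` or ``clone`` are
    considered for collapsing; cultured records are always retained and are
    never used as representatives of environmental duplicates.

    Returns the dereplicated dataset (original record order, representatives
    only) and a map representative id -> sorted member ids (including the
    representative itself).
    """
    if scope not in ("all", "environmental_only"):
        raise ValueError(f"unknown dereplication scope {scope!r}")

    def in_scope(r: BarcodeRecord) -> bool:
        if scope == "all":
            return True
        return r.source_class in ("environmental", "single_cell", "clone")

    by_seq: dict[str, list[str]] = {}
    for r in dataset.records:
        if in_scope(r):
            by_seq.setdefault(r.sequence, []).append(r.record_id)

    multiplicity: dict[str, list[str]] = {}
    drop: set[str] = set()
    for members in by_seq.values():
        members = sorted(members)
        rep = members[0]
        multiplicity[rep] = members
        drop.update(members[1:])
    for r in dataset.records:
        if not in_scope(r):
            multiplicity[r.record_id] = [r.record_id]

    kept = [r for r in dataset.records if r.record_id not in drop]
    # drop dangling clone_parent links to removed duplicates
    kept_ids = {r.record_id for r in kept}
    kept = [
        replace(r, clone_parent="") if r.clone_parent and r.clone_parent not in kept_ids else r
        for r in kept
    ]
    out = BarcodeDataset(kept, dataset.alignment_length, dataset.frame_offset)
    return out, multiplicity
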