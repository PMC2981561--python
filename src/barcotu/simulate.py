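"""Synthetic COI barcode datasets with known ground truth.

The generator builds barcode libraries whose distance structure is planted
*exactly*: substitutions are placed by explicit count at chosen sites (not
per-site probability), so every pairwise distance is a known number of
mismatches over the barcode length and cluster recovery can be asserted
without slack.  At the default 430 nt barcode, one mismatch is 0.233% —
at or below the 0.24% species cut-off — and six mismatches are 1.395%,
at the 1.4% genus bound, so species OTUs are built as cliques of diameter
at most one mismatch separated by at least two, and genus OTUs as cliques
of diameter at most six separated by at least seven.

Two modes are provided:

* :func:`generate` with a plain :class:`GeneratorConfig` — a configurable
  library of genera/species/strains with optional outlier regimes
  (low-divergence genus, hyperdiverse clade-structured genus, cryptic
  complex, split genus), clone sets with or without paralogous copies,
  pseudogenes, RNA-editing stops and an environmental mixture.

* :func:`paper_scale_profile` — a canned configuration reproducing the
  statistical structure of a full environmental survey: 336 cultured reference
  barcodes over 18 genera (including the refractory taxa), 713
  environmental clones collapsing to 603 unique barcodes in 531 species
  OTUs with 51 linked to named cultured species, and a family-scale
  environmental expansion anchored on an unnamed cultured strain (RS24).

All coding sequences are kept stop-free under the configured genetic code
(rejection at the codon level), except for deliberately planted pseudogene
stops and editing-site stops.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import BarcodeDataset, BarcodeRecord, stop_codons_for_table

BASES = "ACGT"


class GenerationError(RuntimeError):
    """Raised when a requested configuration cannot be realized."""


# --------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class EnvironmentalConfig:
    """Environmental mixture settings for the generic generator."""

    n_clones: int = 0
    duplicate_fraction: float = 0.15
    fraction_linked_to_references: float = 0.085
    sites: tuple[str, ...] = ("SiteA", "SiteB")
    depths_m: tuple[float, ...] = (10.0, 100.0)
    seasons: tuple[str, ...] = ("summer", "winter")


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    barcode_length: int = 430
    frame_offset: int = 0
    genetic_code_id: int = 4
    n_genera: int = 18
    species_per_genus: int = 3
    strains_per_species: int = 3
    intra_species_pwd: tuple[float, float] = (0.0, 0.24)
    inter_species_pwd: tuple[float, float] = (0.3, 8.0)
    regimes: frozenset[str] = frozenset()
    paralogue_strains: int = 0
    paralogue_copy_divergence: float = 1.3  # percent between copy classes
    clone_set_size: int = 6  # direct sequence + clones
    pseudogene_rate: float = 0.0
    editing_sites: tuple[int, ...] = ()
    environmental: EnvironmentalConfig | None = None
    profile: str = "generic"

    def __post_init__(self) -> None:
        lo, hi = self.intra_species_pwd
        if not (0 <= lo <= hi <= 100):
            raise GenerationError("intra_species_pwd range out of [0, 100]")
        lo2, hi2 = self.inter_species_pwd
        if not (0 <= lo2 <= hi2 <= 100):
            raise GenerationError("inter_species_pwd range out of [0, 100]")
        if hi > lo2:
            raise GenerationError("intra range must not exceed inter range")
        if self.frame_offset not in (0, 1, 2):
            raise GenerationError("frame_offset must be 0, 1 or 2")


@dataclass
class GroundTruth:
    """Planted truth for a generated dataset."""

    frame_offset: int
    editing_sites: tuple[int, ...]
    species_otu: dict[str, str]  # record_id -> true species-level OTU key
    genus_otu: dict[str, str]  # record_id -> true genus-level OTU key
    pseudogenes: dict[str, int]  # record_id -> planted stop position
    paralogue_strains: set[str]  # strain ids planted with divergent copies
    duplicate_map: dict[str, list[str]]  # representative -> member ids
    statuses: dict[str, str]  # unique env record -> planted status
    expected: dict[str, float | int] = field(default_factory=dict)


def paper_scale_profile(seed: int = 0) -> GeneratorConfig:
    """Canned configuration at the scale of a full environmental survey."""
    return GeneratorConfig(seed=seed, profile="paper_scale")


# --------------------------------------------------------------------------
# sequence primitives (frame 0 internally; the configured frame offset is
# applied by prepending bases at the very end)


def _random_coding(rng: np.random.Generator, length: int, stops: frozenset[str]) -> str:
    codons = []
    n_codons, tail = divmod(length, 3)
    while len(codons) < n_codons:
        codon = "".join(rng.choice(list(BASES), size=3))
        if codon not in stops:
            codons.append(codon)
    tail_bases = "".join(rng.choice(list(BASES), size=tail))
    return "".join(codons) + tail_bases


def _codon_at(seq: str, pos: int) -> tuple[int, str] | None:
    start = (pos // 3) * 3
    if start + 3 <= len(seq):
        return start, seq[start : start + 3]
    return None


def _safe_alts(seq: str, pos: int, stops: frozenset[str], forbid: str = "") -> list[str]:
    """Alternative bases at ``pos`` that do not create an in-frame stop.

    ``forbid`` additionally excludes one base — the ancestral state of a
    substituted site, so re-substituting a variant can never silently
    revert the site and collapse the variant onto the ancestor.
    """
    out = []
    info = _codon_at(seq, pos)
    for b in BASES:
        if b == seq[pos] or b == forbid:
            continue
        if info is not None:
            start, codon = info
            k = pos - start
            new = codon[:k] + b + codon[k + 1 :]
            if new in stops:
                continue
        out.append(b)
    return out


def _substitute(seq: str, sites: list[int], rng, stops) -> str:
    """Substitute each site to a stop-safe alternative base."""
    chars = list(seq)
    for pos in sites:
        alts = _safe_alts("".join(chars), pos, stops)
        if not alts:
            raise GenerationError(f"no stop-safe substitution at site {pos}")
        chars[pos] = alts[rng.integers(len(alts))]
    return "".join(chars)


def _flip_site(seq: str, pos: int, alt_index: int, stops, forbid: str = "") -> str:
    """Deterministically pick the ``alt_index``-th safe alternative at a site."""
    alts = _safe_alts(seq, pos, stops, forbid)
    if alt_index >= len(alts):
        raise GenerationError(f"not enough safe alternatives at site {pos}")
    return seq[:pos] + alts[alt_index] + seq[pos + 1 :]


def _plant_stop(seq: str, codon_index: int, stops) -> tuple[str, int]:
    """Turn one codon into a stop with as few substitutions as possible.

    Returns the mutated sequence and the 0-based position of the codon's
    first nucleotide.
    """
    start = codon_index * 3
    codon = seq[start : start + 3]
    target = None
    best = 4
    for stop in sorted(stops):
        diff = sum(a != b for a, b in zip(codon, stop))
        if diff < best:
            best, target = diff, stop
    return seq[:start] + target + seq[start + 3 :], start


def _site_pool(rng: np.random.Generator, length: int) -> list[int]:
    return list(rng.permutation(length))


class _PoolCursor:
    """Sequential site allocator over a shuffled pool (disjointness by
    construction within one neighbourhood)."""

    def __init__(self, pool: list[int]):
        self.pool = pool
        self.k = 0

    def take(self, n: int) -> list[int]:
        if self.k + n > len(self.pool):
            raise GenerationError("site pool exhausted; barcode too short for plan")
        out = self.pool[self.k : self.k + n]
        self.k += n
        return out


def _take_center(anchor: str, cursor: "_PoolCursor", k: int, rng, stops,
                 min_alts: int = 2) -> tuple[str, list[int]]:
    """Build a species center with at least one substituted site offering
    ``min_alts`` stop-safe non-ancestral alternatives, so variants can
    re-substitute that site without reverting it."""
    for _ in range(50):
        sites = cursor.take(k)
        center = _substitute(anchor, sites, rng, stops)
        if any(
            len(_safe_alts(center, p, stops, forbid=anchor[p])) >= min_alts
            for p in sites
        ):
            return center, sites
    raise GenerationError("could not place a center with a reusable variant site")


def _variant_site(center: str, sites: list[int], n_alts: int, stops,
                  ref: str | None = None) -> int:
    """First substituted site of a species center with enough safe alts.

    With ``ref`` given (the ancestral sequence), the ancestral base at each
    site is excluded from the count.
    """
    for pos in sorted(sites):
        forbid = ref[pos] if ref is not None else ""
        if len(_safe_alts(center, pos, stops, forbid)) >= n_alts:
            return pos
    raise GenerationError("no substituted site offers enough safe alternatives")


# --------------------------------------------------------------------------
# internal builder shared by both modes


class _Builder:
    def __init__(self, cfg: GeneratorConfig):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.stops = stop_codons_for_table(cfg.genetic_code_id)
        self.L = cfg.barcode_length - cfg.frame_offset
        self.records: list[BarcodeRecord] = []
        self.species_otu: dict[str, str] = {}
        self.genus_otu: dict[str, str] = {}
        self.pseudogenes: dict[str, int] = {}
        self.paralogue_strains: set[str] = set()
        self.statuses: dict[str, str] = {}
        self.editing: list[int] = list(cfg.editing_sites)
        self._sp_counter = 0
        self._g_counter = 0
        self._ref_counter = 0
        self._env_counter = 0
        self._cln_counter = 0
        self._strain_counter = 0

    # -- keys and ids

    def new_species_key(self) -> str:
        self._sp_counter += 1
        return f"T-SP-{self._sp_counter:04d}"

    def new_genus_key(self) -> str:
        self._g_counter += 1
        return f"T-G-{self._g_counter:04d}"

    def ref_id(self) -> str:
        self._ref_counter += 1
        return f"REF{self._ref_counter:04d}"

    def env_id(self) -> str:
        self._env_counter += 1
        return f"ENV{self._env_counter:05d}"

    def cln_id(self) -> str:
        self._cln_counter += 1
        return f"CLN{self._cln_counter:04d}"

    def strain(self) -> str:
        self._strain_counter += 1
        return f"S{self._strain_counter:04d}"

    # -- record helpers

    def add(self, record: BarcodeRecord, sp_key: str, g_key: str) -> BarcodeRecord:
        self.records.append(record)
        self.species_otu[record.record_id] = sp_key
        self.genus_otu[record.record_id] = g_key
        return record

    def add_ref(self, seq, genus="", species="", clade="", sp_key=None, g_key=None,
                strain=None) -> BarcodeRecord:
        rid = self.ref_id()
        rec = BarcodeRecord(
            record_id=rid, sequence=seq, source_class="cultured",
            genus=genus, species=species, clade=clade,
            strain_id=strain or self.strain(), accession=f"SYN{rid}",
        )
        return self.add(rec, sp_key or self.new_species_key(), g_key or self.new_genus_key())

    def add_env(self, seq, sp_key, g_key, status, source_class="environmental") -> BarcodeRecord:
        rid = self.env_id()
        rec = BarcodeRecord(
            record_id=rid, sequence=seq, source_class=source_class,
            accession=f"SYN{rid}",
        )
        self.statuses[rid] = status
        return self.add(rec, sp_key, g_key)

    def anchor(self) -> str:
        return _random_coding(self.rng, self.L, self.stops)

    # -- finalization

    def finalize(self, expected: dict) -> tuple[BarcodeDataset, GroundTruth]:
        f = self.cfg.frame_offset
        records = self.records
        if f:
            prefix = "".join(self.rng.choice(list(BASES), size=f))
            records = [replace(r, sequence=prefix + r.sequence) for r in records]
            self.editing = [p + f for p in self.editing]
            self.pseudogenes = {k: v + f for k, v in self.pseudogenes.items()}

        # duplicate map from exact sequence identity among env-class records
        by_seq: dict[str, list[str]] = {}
        for r in records:
            if r.source_class in ("environmental", "single_cell"):
                by_seq.setdefault(r.sequence, []).append(r.record_id)
        dup_map = {sorted(v)[0]: sorted(v) for v in by_seq.values()}

        dataset = BarcodeDataset(
            records, alignment_length=self.cfg.barcode_length, frame_offset=f
        )
        truth = GroundTruth(
            frame_offset=f,
            editing_sites=tuple(sorted(self.editing)),
            species_otu=dict(self.species_otu),
            genus_otu=dict(self.genus_otu),
            pseudogenes=dict(self.pseudogenes),
            paralogue_strains=set(self.paralogue_strains),
            duplicate_map=dup_map,
            statuses=dict(self.statuses),
            expected=expected,
        )
        _verify(dataset, truth)
        return dataset, truth


# --------------------------------------------------------------------------
# generation-time verification of the planted structure


def _mismatch_matrix(seqs: list[str]) -> np.ndarray:
    arr = np.stack(
        [np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs]
    )
    matches = np.zeros((len(seqs), len(seqs)))
    for b in BASES:
        ind = (arr == ord(b)).astype(np.float64)
        matches += ind @ ind.T
    return len(seqs[0]) - np.rint(matches).astype(np.int64)


def _verify(dataset: BarcodeDataset, truth: GroundTruth) -> None:
    """Check that realized mismatch counts honour the planted OTU geometry.

    Clone-library records and planted pseudogenes are exempt (they are
    screened out before clustering), as are records whose truth keys mark
    them unconstrained.
    """
    core = [
        r
        for r in dataset.records
        if r.source_class != "clone" and r.record_id not in truth.pseudogenes
    ]
    if len(core) < 2:
        return
    mm = _mismatch_matrix([r.sequence for r in core])
    sp = np.array([truth.species_otu[r.record_id] for r in core])
    same_sp = sp[:, None] == sp[None, :]
    off = ~np.eye(len(core), dtype=bool)
    if (mm[same_sp & off] > 1).any():
        raise GenerationError("species clique diameter exceeded one mismatch")
    if ((mm < 2) & ~same_sp).any():
        raise GenerationError("distinct species closer than two mismatches")
    g = np.array([truth.genus_otu[r.record_id] for r in core])
    same_g = g[:, None] == g[None, :]
    if (mm[same_g & off] > 6).any():
        raise GenerationError("genus clique diameter exceeded six mismatches")
    if ((mm < 7) & ~same_g).any():
        raise GenerationError("distinct genus OTUs closer than seven mismatches")


# --------------------------------------------------------------------------
# generic mode


def _generate_generic(cfg: GeneratorConfig) -> tuple[BarcodeDataset, GroundTruth]:
    b = _Builder(cfg)
    L = b.L
    lo, hi = cfg.inter_species_pwd
    k_lo = max(1, int(np.ceil(lo * L / 200)))
    k_hi = max(k_lo, int(np.floor(hi * L / 200)))
    # keep genus cliques intact (diameter <= 6 mismatches) when possible
    k_hi_clique = min(k_hi, 3)
    intra_max_mm = int(np.floor(cfg.intra_species_pwd[1] * L / 100))

    regimes = set(cfg.regimes)
    strain_records: list[BarcodeRecord] = []

    def build_genus(genus_name: str, species_names: list[str], k_range=(k_lo, k_hi_clique),
                    shared_center_all=False, extra_split=None):
        anchor = b.anchor()
        cursor = _PoolCursor(_site_pool(b.rng, L))
        g_key = b.new_genus_key()
        shared = None
        for s_i, sp_name in enumerate(species_names):
            if shared_center_all and shared is not None:
                center, sites, sp_key = shared
            else:
                k = int(b.rng.integers(k_range[0], k_range[1] + 1))
                center, sites = _take_center(anchor, cursor, k, b.rng, b.stops)
                sp_key = b.new_species_key()
                if shared_center_all:
                    shared = (center, sites, sp_key)
            this_g = g_key
            if extra_split is not None and s_i == extra_split[0]:
                # cryptic split: a far subgroup under the same species name
                far_sites = cursor.take(extra_split[1])
                far_center = _substitute(center, far_sites, b.rng, b.stops)
                far_key = b.new_species_key()
                far_g = b.new_genus_key() if extra_split[1] > 6 else g_key
                for s in range(cfg.strains_per_species):
                    b.add_ref(far_center, genus=genus_name, species=sp_name,
                              sp_key=far_key, g_key=far_g)
            for s in range(cfg.strains_per_species):
                seq = center
                if intra_max_mm >= 1 and s == cfg.strains_per_species - 1:
                    v = _variant_site(center, sites, 1, b.stops, ref=anchor)
                    seq = _flip_site(center, v, 0, b.stops, forbid=anchor[v])
                rec = b.add_ref(seq, genus=genus_name, species=sp_name,
                                sp_key=sp_key, g_key=this_g)
                strain_records.append(rec)

    n_special = sum(
        r in regimes
        for r in ("low_divergence_genus", "hyperdiverse_clades", "cryptic_complex", "split_genus")
    )
    n_plain = max(0, cfg.n_genera - n_special)
    for gi in range(n_plain):
        names = [f"species{gi + 1}_{j + 1}" for j in range(cfg.species_per_genus)]
        build_genus(f"Genus{gi + 1:02d}", names)

    if "low_divergence_genus" in regimes:
        names = [f"lowdiv_{j + 1}" for j in range(max(2, cfg.species_per_genus))]
        build_genus("Lowdivium", names, shared_center_all=True)
    if "cryptic_complex" in regimes:
        build_genus("Crypticium", ["complexa", "plainspecies"], extra_split=(0, 7))
    if "split_genus" in regimes:
        anchor = b.anchor()
        cursor = _PoolCursor(_site_pool(b.rng, L))
        g1, g2 = b.new_genus_key(), b.new_genus_key()
        group_offset = _substitute(anchor, cursor.take(20), b.rng, b.stops)
        for base, g_key, names in (
            (anchor, g1, ["benthica", "littoralis"]),
            (group_offset, g2, ["planktonica", "oceanica"]),
        ):
            for sp_name in names:
                sites = cursor.take(int(b.rng.integers(1, 3)))
                center = _substitute(base, sites, b.rng, b.stops)
                sp_key = b.new_species_key()
                for _ in range(cfg.strains_per_species):
                    strain_records.append(
                        b.add_ref(center, genus="Splitium", species=sp_name,
                                  sp_key=sp_key, g_key=g_key)
                    )
    if "hyperdiverse_clades" in regimes:
        anchor = b.anchor()
        cursor = _PoolCursor(_site_pool(b.rng, L))
        for ci, (clade, k) in enumerate(zip("ABDF", (7, 8, 9, 10))):
            center = _substitute(anchor, cursor.take(k), b.rng, b.stops)
            sp_key, g_key = b.new_species_key(), b.new_genus_key()
            for _ in range(cfg.strains_per_species):
                b.add_ref(center, genus="Cladium", clade=clade, sp_key=sp_key, g_key=g_key)
            if clade == "D":
                far = _substitute(center, cursor.take(20), b.rng, b.stops)
                sp2, g2 = b.new_species_key(), b.new_genus_key()
                for _ in range(cfg.strains_per_species):
                    b.add_ref(far, genus="Cladium", clade=clade, sp_key=sp2, g_key=g2)

    # pseudogenes: convert a planted fraction of reference records
    if cfg.pseudogene_rate > 0:
        n_pseudo = int(round(cfg.pseudogene_rate * len(b.records)))
        order = b.rng.permutation(len(b.records))[:n_pseudo]
        n_codons = L // 3
        for idx in sorted(order):
            r = b.records[idx]
            codon_index = int(b.rng.integers(5, n_codons - 5))
            while codon_index * 3 in cfg.editing_sites:
                codon_index += 1
            seq, pos = _plant_stop(r.sequence, codon_index, b.stops)
            b.records[idx] = replace(r, sequence=seq)
            b.pseudogenes[r.record_id] = pos

    # editing-site stops: plant a stop at each configured editing site in
    # every strain of the first species (shared by the whole species)
    for pos in cfg.editing_sites:
        codon_index = pos // 3
        first_key = b.species_otu[strain_records[0].record_id] if strain_records else None
        for i, r in enumerate(b.records):
            if b.species_otu[r.record_id] == first_key and r.record_id not in b.pseudogenes:
                seq, _ = _plant_stop(r.sequence, codon_index, b.stops)
                b.records[i] = replace(r, sequence=seq)

    # clone sets, optionally with paralogous copy classes
    copy_mm = max(1, int(round(cfg.paralogue_copy_divergence * L / 100)))
    eligible = [r for r in b.records if r.source_class == "cultured"
                and r.record_id not in b.pseudogenes]
    for p in range(cfg.paralogue_strains):
        parent = eligible[p % len(eligible)]
        b.paralogue_strains.add(parent.strain_id)
        pool = _PoolCursor(_site_pool(b.rng, L))
        far = _substitute(parent.sequence, pool.take(copy_mm), b.rng, b.stops)
        n_clones = cfg.clone_set_size - 1
        for c in range(n_clones):
            seq = parent.sequence if c < (n_clones + 1) // 2 - 1 else far
            rid = b.cln_id()
            rec = BarcodeRecord(
                record_id=rid, sequence=seq, source_class="clone",
                genus=parent.genus, species=parent.species, clade=parent.clade,
                strain_id=parent.strain_id, clone_parent=parent.record_id,
            )
            b.add(rec, b.species_otu[parent.record_id], b.genus_otu[parent.record_id])

    # environmental mixture
    n_linked = 0
    if cfg.environmental is not None and cfg.environmental.n_clones > 0:
        env = cfg.environmental
        n_dup = int(round(env.duplicate_fraction * env.n_clones))
        n_unique = env.n_clones - n_dup
        n_linked = int(round(env.fraction_linked_to_references * n_unique))
        named_centers = []  # one strain (the species center) per named species
        seen = set()
        for r in strain_records:
            key = b.species_otu[r.record_id]
            if key not in seen:
                seen.add(key)
                named_centers.append(r)
        n_linked = min(n_linked, len(named_centers))
        uniques = []
        for i in range(n_unique):
            if i < n_linked and i < len(named_centers):
                # a linked query carries exactly the species-center barcode
                # (one species per query, so linked uniques stay unique)
                ref = named_centers[i]
                rec = b.add_env(ref.sequence, b.species_otu[ref.record_id],
                                b.genus_otu[ref.record_id], "species_match")
            else:
                seq = b.anchor()
                rec = b.add_env(seq, b.new_species_key(), b.new_genus_key(), "unidentified")
            rec = _with_env_metadata(b, rec, env, i)
            uniques.append(rec)
        for i in range(n_dup):
            src = uniques[i % len(uniques)]
            rec = b.add_env(src.sequence, b.species_otu[src.record_id],
                            b.genus_otu[src.record_id], b.statuses[src.record_id])
            _with_env_metadata(b, rec, env, n_unique + i)

    expected = {
        "n_records": len(b.records),
        "n_linked_uniques": n_linked,
    }
    return b.finalize(expected)


def _with_env_metadata(b: _Builder, rec: BarcodeRecord, env: EnvironmentalConfig,
                       i: int) -> BarcodeRecord:
    new = replace(
        rec,
        site=env.sites[i % len(env.sites)],
        depth_m=float(env.depths_m[i % len(env.depths_m)]),
        season=env.seasons[i % len(env.seasons)],
    )
    b.records[b.records.index(rec)] = new
    return new


# --------------------------------------------------------------------------
# survey-scale profile

# reference library plan: genus -> list of species entries
#   (species, clade, k, n_strains, n_variants, identical_to, group_offset, split)
# k: substitutions from the genus anchor; identical_to: share the center of a
# previously built species; group_offset: extra shared substitutions placed
# before k (deep within-genus split); split: (n_extra_strains, extra_mm)
# subgroup under the same name.


def _profile_reference_plan():
    clean = [
        ("Akashiwo", [("sanguinea", 1, 3), ("rhodophila", 2, 3)]),
        ("Gonyaulax", [("spinifera", 1, 3), ("polygramma", 2, 3)]),
        ("Gambierdiscus", [("toxicus", 1, 3), ("belizeanus", 2, 3)]),
        ("Peridinium", [("quinquecorne", 1, 3), ("willei", 2, 3), ("cinctum", 2, 3)]),
        ("Pfiesteria", [("piscicida", 1, 3), ("shumwayae", 2, 3)]),
        ("Polarella", [("glacialis", 1, 2), ("borealis", 2, 2)]),
        ("Thecadinium", [("yashimaense", 1, 2), ("mucosum", 2, 2)]),
        ("Woloszynskia", [("halophila", 1, 2), ("pseudopalustris", 2, 2)]),
        ("Gyrodinium", [("spirale", 1, 3), ("fusiforme", 2, 3)]),
        ("Adenoides", [("eludens", 1, 3), ("kofoidii", 2, 3)]),
        ("Karlodinium", [("veneficum", 1, 4), ("micrum", 2, 4)]),
    ]
    return clean


def _generate_profile(cfg: GeneratorConfig) -> tuple[BarcodeDataset, GroundTruth]:
    b = _Builder(cfg)
    L = b.L
    rng, stops = b.rng, b.stops

    # ---- named reference library -------------------------------------
    # registry: (genus, species) -> dict(center, sites, sp_key, g_key, variants_used)
    reg: dict[tuple[str, str], dict] = {}
    genus_cursors: dict[str, _PoolCursor] = {}
    genus_anchors: dict[str, str] = {}

    def ensure_genus(genus):
        if genus not in genus_anchors:
            genus_anchors[genus] = b.anchor()
            genus_cursors[genus] = _PoolCursor(_site_pool(rng, L))
        return genus_anchors[genus], genus_cursors[genus]

    def build_species(genus, species, k, n_strains, clade="", identical_to=None,
                      base=None, g_key=None, n_variants=1, anchor_override=None):
        if identical_to is not None:
            src = reg[identical_to]
            entry = dict(src)
            entry["variants_used"] = src["variants_used"]  # shared alt counter
            center, sites, sp_key = src["center"], src["sites"], src["sp_key"]
            g_key = src["g_key"]
        else:
            anchor, cursor = (
                (anchor_override, genus_cursors[genus])
                if anchor_override is not None
                else ensure_genus(genus)
            )
            if base is not None:
                anchor = base
            center, sites = _take_center(anchor, cursor, k, rng, stops)
            sp_key = b.new_species_key()
            g_key = g_key or b.new_genus_key()
            entry = dict(center=center, sites=sites, sp_key=sp_key, g_key=g_key,
                         variants_used=[0], anchor=anchor)
            reg[(genus, species or f"clade{clade}")] = entry
        made = []
        for s in range(n_strains):
            seq = center
            if n_variants and s == n_strains - 1:
                v = _variant_site(center, sites, 2, stops, ref=entry["anchor"])
                alt = entry["variants_used"][0]
                entry["variants_used"][0] += 1
                seq = _flip_site(center, v, alt, stops, forbid=entry["anchor"][v])
            made.append(
                b.add_ref(seq, genus=genus, species=species, clade=clade,
                          sp_key=sp_key, g_key=g_key)
            )
        return made

    for genus, species_list in _profile_reference_plan():
        shared_g = b.new_genus_key()
        for species, k, n_strains in species_list:
            build_species(genus, species, k, n_strains, g_key=shared_g)

    # Karenia: two species with identical barcodes plus one distinct
    kar_g = b.new_genus_key()
    build_species("Karenia", "mikimotoi", 1, 4, g_key=kar_g)
    build_species("Karenia", "brevis", 0, 4, identical_to=("Karenia", "mikimotoi"))
    build_species("Karenia", "papilionacea", 3, 3, g_key=kar_g)

    # Scrippsiella: identical species pair, a clean species, and a cryptic
    # species complex split well beyond the species cut-off
    scr_g = b.new_genus_key()
    build_species("Scrippsiella", "precaria", 1, 3, g_key=scr_g, n_variants=0)
    build_species("Scrippsiella", "lachrymosa", 0, 2,
                  identical_to=("Scrippsiella", "precaria"), n_variants=0)
    build_species("Scrippsiella", "sweeneyae", 2, 3, g_key=scr_g)
    troch = build_species("Scrippsiella", "trochoidea", 2, 4, g_key=scr_g)
    troch_center = reg[("Scrippsiella", "trochoidea")]
    far_sites = genus_cursors["Scrippsiella"].take(7)
    far_center = _substitute(troch_center["center"], far_sites, rng, stops)
    far_key, far_g = b.new_species_key(), b.new_genus_key()
    reg[("Scrippsiella", "trochoidea-B")] = dict(
        center=far_center, sites=troch_center["sites"] + far_sites,
        sp_key=far_key, g_key=far_g, variants_used=[0],
        anchor=genus_anchors["Scrippsiella"])
    for _ in range(4):
        b.add_ref(far_center, genus="Scrippsiella", species="trochoidea",
                  sp_key=far_key, g_key=far_g)

    build_species("Thoracosphaera", "heimii", 1, 3)

    # Prorocentrum: benthic and planktonic groups split far apart
    pro_anchor, pro_cursor = ensure_genus("Prorocentrum")
    pro_g1 = b.new_genus_key()
    build_species("Prorocentrum", "lima", 1, 3, g_key=pro_g1)
    build_species("Prorocentrum", "levis", 2, 2, g_key=pro_g1, n_variants=0)
    plank_base = _substitute(pro_anchor, pro_cursor.take(20), rng, stops)
    pro_g2 = b.new_genus_key()
    build_species("Prorocentrum", "minimum", 1, 3, base=plank_base, g_key=pro_g2)
    build_species("Prorocentrum", "micans", 2, 3, base=plank_base, g_key=pro_g2)
    build_species("Prorocentrum", "triestinum", 2, 2, base=plank_base, g_key=pro_g2,
                  n_variants=0)

    # RNA editing: every P. minimum barcode carries a stop at an editing site
    pmin = reg[("Prorocentrum", "minimum")]
    # find a codon one substitution away from a stop, clear of the species'
    # planted substitution sites, so the clique geometry stays intact
    used_sites = set(pmin["sites"])
    edit_codon = None
    for ci in range(20, L // 3 - 5):
        if any(p // 3 == ci for p in used_sites):
            continue
        cand, _ = _plant_stop(pmin["center"], ci, stops)
        if sum(a != b_ for a, b_ in zip(pmin["center"], cand)) == 1:
            edit_codon = ci
            break
    if edit_codon is None:
        raise GenerationError("no codon admits a single-substitution stop")
    edited_center, edit_pos = _plant_stop(pmin["center"], edit_codon, stops)
    b.editing.append(edit_pos)
    pmin_ids = [r.record_id for r in b.records
                if r.genus == "Prorocentrum" and r.species == "minimum"]
    for i, r in enumerate(b.records):
        if r.record_id in pmin_ids:
            seq, _ = _plant_stop(r.sequence, edit_codon, stops)
            b.records[i] = replace(r, sequence=seq)
    pmin["center"] = edited_center

    # Pyrocystis: two species at deep within-genus divergence
    pyr_anchor, _ = ensure_genus("Pyrocystis")
    build_species("Pyrocystis", "lunula", 1, 2, g_key=b.new_genus_key())
    build_species("Pyrocystis", "noctiluca", 9, 2, g_key=b.new_genus_key())

    # Gymnodinium: a sensu stricto pair plus paraphyletic satellites
    gym_g = b.new_genus_key()
    build_species("Gymnodinium", "catenatum", 1, 4, g_key=gym_g)
    build_species("Gymnodinium", "impudicum", 2, 3, g_key=gym_g)
    aur_anchor = b.anchor()
    genus_anchors["Gymnodinium-para1"] = aur_anchor
    genus_cursors["Gymnodinium-para1"] = _PoolCursor(_site_pool(rng, L))
    build_species("Gymnodinium", "aureolum", 1, 2, n_variants=0,
                  anchor_override=aur_anchor, g_key=b.new_genus_key())
    # second paraphyletic species identical to the first
    build_species("Gymnodinium", "instriatum", 0, 2,
                  identical_to=("Gymnodinium", "aureolum"), n_variants=0)
    sim_anchor = b.anchor()
    genus_anchors["Gymnodinium-para2"] = sim_anchor
    genus_cursors["Gymnodinium-para2"] = _PoolCursor(_site_pool(rng, L))
    build_species("Gymnodinium", "simplex", 1, 2, n_variants=0,
                  anchor_override=sim_anchor, g_key=b.new_genus_key())

    # Alexandrium: a species complex with identical barcodes plus one
    # divergent species
    alex_g = b.new_genus_key()
    build_species("Alexandrium", "tamarense", 1, 2, g_key=alex_g, n_variants=0)
    for sp in ("catenella", "minutum", "fundyense", "affine", "ostenfeldii", "insuetum"):
        build_species("Alexandrium", sp, 0, 2,
                      identical_to=("Alexandrium", "tamarense"), n_variants=0)
    build_species("Alexandrium", "pseudogonyaulax", 10, 6, g_key=b.new_genus_key())

    # Protoceratium / Lingulodinium: identical barcodes across genera
    build_species("Protoceratium", "reticulatum", 1, 3, n_variants=0)
    build_species("Lingulodinium", "polyedrum", 0, 3,
                  identical_to=("Protoceratium", "reticulatum"), n_variants=0)

    # Symbiodinium: clade-structured, hyperdiverse; clade D split in two
    sym_anchor, sym_cursor = ensure_genus("Symbiodinium")
    for clade, k, n in (("A", 7, 8), ("B", 8, 8), ("C", 9, 4), ("E", 10, 4), ("F", 11, 8)):
        build_species("Symbiodinium", "", k, n, clade=clade)
    d_entry_members = build_species("Symbiodinium", "", 12, 3, clade="D")
    d_center = reg[("Symbiodinium", "cladeD")]
    d_far = _substitute(d_center["center"], sym_cursor.take(20), rng, stops)
    d2_key, d2_g = b.new_species_key(), b.new_genus_key()
    for _ in range(3):
        b.add_ref(d_far, genus="Symbiodinium", clade="D", sp_key=d2_key, g_key=d2_g)

    named_refs = list(b.records)
    n_named = len(named_refs)

    # ---- unnamed cultured records ------------------------------------
    # the family anchor: an unnamed cultured strain sister to Karenia
    kar_anchor, kar_cursor = genus_anchors["Karenia"], genus_cursors["Karenia"]
    rs24_seq, rs24_sites = _take_center(kar_anchor, kar_cursor, 15, rng, stops)
    rs24_sp, rs24_g = b.new_species_key(), b.new_genus_key()
    rs24 = b.add_ref(rs24_seq, sp_key=rs24_sp, g_key=rs24_g, strain="RS24")

    # unnamed duplicates of named centers and novel unnamed isolates
    named_center_entries = [v for v in reg.values()]
    for i in range(80):
        src = named_center_entries[i % len(named_center_entries)]
        b.add_ref(src["center"], sp_key=src["sp_key"], g_key=src["g_key"])
    for _ in range(66):
        b.add_ref(b.anchor())
    n_refs = len(b.records)

    # ---- clone sets for the paralogue/pseudogene screen --------------
    def clone_set(genus, species, clade, n_clones, paralogue_mm=0, one_off=True):
        parent = next(
            r for r in named_refs
            if r.genus == genus and r.species == species and r.clade == clade
        )
        if paralogue_mm:
            b.paralogue_strains.add(parent.strain_id)
        pool = [p for p in range(L)
                if len(_safe_alts(parent.sequence, p, stops)) >= 1]
        far = None
        if paralogue_mm:
            far_sites = list(rng.choice(pool, size=paralogue_mm, replace=False))
            far = _substitute(parent.sequence, far_sites, rng, stops)
        for c in range(n_clones):
            if far is not None and c >= n_clones - 3:
                seq = far
            elif one_off and c == n_clones - 1 and far is None:
                v = pool[int(rng.integers(len(pool)))]
                seq = _flip_site(parent.sequence, v, 0, stops)
            else:
                seq = parent.sequence
            rid = b.cln_id()
            rec = BarcodeRecord(
                record_id=rid, sequence=seq, source_class="clone",
                genus=parent.genus, species=parent.species, clade=parent.clade,
                strain_id=parent.strain_id, clone_parent=parent.record_id,
            )
            b.add(rec, b.species_otu[parent.record_id], b.genus_otu[parent.record_id])
        return parent

    clone_set("Scrippsiella", "precaria", "", 3)
    clone_set("Scrippsiella", "trochoidea", "", 5)
    clone_set("Prorocentrum", "lima", "", 5)
    clone_set("Prorocentrum", "minimum", "", 5)
    clone_set("Prorocentrum", "micans", "", 5)
    clone_set("Symbiodinium", "", "B", 5)
    # the CCMP421-like strain: two divergent copy classes among its clones
    paralogue_parent = clone_set("Symbiodinium", "", "E", 5, paralogue_mm=9)

    # ---- environmental survey ----------------------------------------
    # block 1: uniques sharing species OTUs with named references
    linked_keys = [
        (g, s) for (g, s) in reg
        if g not in ("Karenia", "Karlodinium")
        and (g, s) not in (("Symbiodinium", "cladeD"),)
        and s not in ("lachrymosa", "instriatum", "brevis", "catenella", "minutum",
                      "fundyense", "affine", "ostenfeldii", "insuetum", "polyedrum")
    ]
    linked_keys = sorted(linked_keys)[:45]
    if len(linked_keys) != 45:
        raise GenerationError(f"expected 45 linkable species, got {len(linked_keys)}")
    # a substituted site supports at most two non-ancestral variants, so the
    # species with no reference variant (counter still zero) are the ones
    # that can host two environmental uniques; six of them do
    doubles = [k for k in linked_keys if reg[k]["variants_used"][0] == 0][:6]
    if len(doubles) != 6:
        raise GenerationError(f"expected 6 double-linked species, got {len(doubles)}")
    block1 = []
    for key in linked_keys:
        entry = reg[key]
        n_uniques = 2 if key in doubles else 1
        for u in range(n_uniques):
            v = _variant_site(entry["center"], entry["sites"], 2, stops,
                              ref=entry["anchor"])
            alt = entry["variants_used"][0]
            entry["variants_used"][0] += 1
            seq = _flip_site(entry["center"], v, alt, stops,
                             forbid=entry["anchor"][v])
            block1.append(
                b.add_env(seq, entry["sp_key"], entry["g_key"], "species_match")
            )
    _plant_duplicates(b, block1, 40)

    # block 2: the family-scale expansion around the anchor strain
    rs24_uniques = [b.add_env(rs24_seq, rs24_sp, rs24_g, "unidentified")]
    v = _variant_site(rs24_seq, rs24_sites, 2, stops, ref=kar_anchor)
    for alt in range(2):
        rs24_uniques.append(
            b.add_env(_flip_site(rs24_seq, v, alt, stops, forbid=kar_anchor[v]),
                      rs24_sp, rs24_g, "unidentified")
        )
    _plant_duplicates(b, rs24_uniques, 23)

    novel_uniques = []
    for i in range(87):
        k = 2 + (i % 2)
        sites = kar_cursor.take(k)
        center = _substitute(rs24_seq, sites, rng, stops)
        sp_key = b.new_species_key()
        novel_uniques.append(b.add_env(center, sp_key, rs24_g, "unidentified"))
        if i < 3:
            vv = _variant_site(center, sites, 1, stops, ref=rs24_seq)
            novel_uniques.append(
                b.add_env(_flip_site(center, vv, 0, stops, forbid=rs24_seq[vv]),
                          sp_key, rs24_g, "unidentified")
            )
    _plant_duplicates(b, novel_uniques, 6)

    # family-level members beyond the anchor's genus OTU
    family_only = []
    rs24_site_set = set(rs24_sites)
    free_sites = [p for p in range(L) if p not in rs24_site_set]
    fam_centers: list[set[int]] = []
    for i in range(48):
        k = 10 + (i % 11)
        for _attempt in range(100):
            sites = set(rng.choice(free_sites, size=k, replace=False))
            if all(len(sites ^ other) > 6 for other in fam_centers):
                break
        else:
            raise GenerationError("could not separate family-level species")
        fam_centers.append(sites)
        center = _substitute(rs24_seq, sorted(sites), rng, stops)
        sp_key, g_key = b.new_species_key(), b.new_genus_key()
        family_only.append(b.add_env(center, sp_key, g_key, "unidentified"))
        if i < 2:
            vv = _variant_site(center, sorted(sites), 1, stops, ref=rs24_seq)
            family_only.append(
                b.add_env(_flip_site(center, vv, 0, stops, forbid=rs24_seq[vv]),
                          sp_key, g_key, "unidentified")
            )
    _plant_duplicates(b, family_only, 5)

    # block 3a: genus-level-only queries inside clean reference genera
    genus_linked = []
    clean_genera = [g for g, _ in _profile_reference_plan() if g != "Karlodinium"]
    for i in range(30):
        genus = clean_genera[i % len(clean_genera)]
        anchor, cursor = genus_anchors[genus], genus_cursors[genus]
        site = cursor.take(1)
        seq = _substitute(anchor, site, rng, stops)
        g_key = next(
            b.genus_otu[r.record_id] for r in named_refs if r.genus == genus
        )
        genus_linked.append(b.add_env(seq, b.new_species_key(), g_key, "genus_match"))

    # block 3b: diverse unlinked environmental species
    block3 = []
    for i in range(320):
        center = b.anchor()
        sp_key, g_key = b.new_species_key(), b.new_genus_key()
        block3.append(b.add_env(center, sp_key, g_key, "unidentified",
                                source_class="environmental"))
        if i < 59:
            pool = [p for p in range(L) if len(_safe_alts(center, p, stops)) >= 1]
            vv = pool[int(rng.integers(len(pool)))]
            block3.append(b.add_env(_flip_site(center, vv, 0, stops), sp_key, g_key,
                                    "unidentified"))
    _plant_duplicates(b, block3, 36)

    # ---- environmental metadata (sites, depths, seasons, single cells)
    env_records = [r for r in b.records if r.source_class == "environmental"]
    assert len(env_records) == 713, len(env_records)
    schedule = (
        [("Saanich Inlet", d, s)
         for d, s in zip([10, 100, 120, 200] * 144, (["summer"] * 4 + ["winter"] * 4) * 72)][:574]
        + [("Maine coast", 5, "summer")] * 86
        + [("Guadeloupe", 5, "summer")] * 29
        + [("Vancouver Island", 0, "summer")] * 24
    )
    env_ids = [r.record_id for r in env_records]
    for rid, (site, depth, season) in zip(env_ids, schedule):
        i = next(k for k, r in enumerate(b.records) if r.record_id == rid)
        r = b.records[i]
        source = "single_cell" if site == "Vancouver Island" else "environmental"
        b.records[i] = replace(r, site=site, depth_m=float(depth), season=season,
                               source_class=source)
        if rid in b.statuses and source == "single_cell":
            pass  # single cells keep their planted status

    expected = {
        "n_references": n_refs,
        "n_named_reference_strains": n_named,
        "n_env_clones": 713,
        "n_env_unique": 603,
        "n_species_otus": 531,
        "n_species_linked_uniques": 51,
        "n_genus_linked_uniques": 30,
        "family_clones": 177,
        "family_genus_with_anchor": 122,
        "family_species_with_anchor": 26,
        "family_species_otus_with_anchor": 88,
        "anchor_id": rs24.record_id,
        "paralogue_strain": paralogue_parent.strain_id,
        "family_reference_genera": ("Karenia", "Karlodinium"),
    }
    return b.finalize(expected)


def _plant_duplicates(b: _Builder, uniques: list[BarcodeRecord], n_dup: int) -> None:
    """Append exact duplicates of the given unique records, round-robin."""
    for i in range(n_dup):
        src = uniques[i % len(uniques)]
        b.add_env(src.sequence, b.species_otu[src.record_id],
                  b.genus_otu[src.record_id], b.statuses[src.record_id])


# --------------------------------------------------------------------------


def generate(cfg: GeneratorConfig) -> tuple[BarcodeDataset, GroundTruth]:
    """Generate a dataset and its ground truth from a configuration."""
    if cfg.profile == "paper_scale":
        return _generate_profile(cfg)
    if cfg.profile != "generic":
        raise GenerationError(f"unknown profile {cfg.profile!r}")
    return _generate_generic(cfg)
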