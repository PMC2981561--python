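# Methods

This note records the methodological conventions, default parameters and
numerical choices used throughout `barcotu`.

## Distance model

**Uncorrected p-distance.** For two aligned sequences, the distance is
`100 × mismatches / comparable_sites`, where a site is comparable only when
both sequences carry an unambiguous base (A, C, G or T). IUPAC ambiguity
codes and gaps are removed pairwise (pairwise deletion), so the denominator
varies by pair. No multiple-hit correction is applied: at the divergences
relevant to species delimitation (< ~10%), corrections change distances by
less than the biological noise and would blur the empirical thresholds.
Transitions and transversions are weighted equally.

A pair with fewer than `min_overlap` comparable sites (default 100) is an
error, not a silent zero — short overlaps produce unstable percentages.

**Implementation.** The full matrix is computed with four per-base indicator
matrix products (one per base) plus a validity product, giving the match
count and comparable-site count for every pair at once. Counts are rounded
with `np.rint` before division so the integer arithmetic survives the float
detour bit-exactly; the result equals a per-site loop to 1e-12.

## Trimming and reading frame

Sequences amplified with fixed nested primers share their 5' end and vary
only in 3' extent, so the common window is a truncation to the shortest
sequence. The reading frame (offset 0, 1 or 2) is chosen to minimise the
total number of in-frame stop codons over the named cultured records —
functional COI from healthy cultures must translate cleanly. The default
genetic code is NCBI table 4 (mold/protozoan mitochondrial), under which
TGA encodes tryptophan and only TAA/TAG are stops.

## Pseudogene screen

A record fails when its in-frame translation contains a stop codon, with
two exemptions:

* **Configured editing sites** — positions where RNA editing repairs the
  transcript post-transcriptionally.
* **Inferred editing sites** — a stop at the same position in two or more
  strains of the same named species. Independent pseudogene decay does not
  repeat a position across strains; shared stops indicate editing. Once
  inferred, the exemption applies to every record (including environmental
  ones), and the inference is logged.

Codons containing ambiguity codes translate to X and never count as stops.

## Paralogue test

For strains with cloned amplicon libraries, the mean p-distance over all
unordered pairs in the clone set (clones plus the direct sequence) is
compared to the species cut-off (0.24%). Clean strains — PCR/cloning error
only — sit at or below ~0.2%; a strain carrying two divergent gene-copy
classes shows a mean several-fold higher (two classes ~2% apart with a
balanced clone set give a mean near 1.3%).

## OTU delineation

**Complete-linkage clustering.** Agglomeration merges the pair of clusters
with the smallest maximum cross-distance first, stopping when no merge can
keep the maximum intra-cluster distance at or below the threshold. The
boundary is inclusive ("0.24% or less"). Complete linkage guarantees the
defining invariant — every member within the threshold of every other
member — which single linkage (chaining) would not. Ties are broken by the
lexicographically smallest member id, making the partition independent of
input order.

**Thresholds.** 0.24% at the species level; 1.4% at the genus level by
default. For identification, each genus gets an empirical bound (the
maximum observed congeneric inter-species PWD, capped at 5.9%); genera with
outlier internal structure (deep splits, clade-organised genera) fall back
to the 1.4% default.

**Ambiguity resolution.** After clustering, a record that lies within the
threshold of members of two OTUs, or of only part of its own OTU, is split
off; the flagged records are re-clustered among themselves and end up in
smaller groups or as singletons. Resolution runs before naming, so names
attach to stable groups.

## Calibration

From the named reference strains, two distributions are computed: PWDs
between conspecific strains (intra-species) and between congeneric species
(inter-species). The *assignable fraction* at cut-off *c* is the share of
named strains whose most distant conspecific is ≤ *c* while the closest
heterospecific named strain (any genus) is > *c*.

Default exclusions, applied to a second calibration pass: *Alexandrium*
(COI too conserved to separate its species), *Protoceratium* and
*Lingulodinium* (indistinguishable at genus level), *Symbiodinium*
(organised into clades, not binomial species), and all *Gymnodinium*
except *G. catenatum* and *G. impudicum* (the rest of the genus is
paraphyletic). Unnamed strains never enter calibration but remain in the
pipeline.

## Identification

Environmental and single-cell records are dereplicated (exact sequence
identity; the representative is the lexicographically smallest id; cultured
records are never collapsed) and then assigned:

* **species_match** — shares a species-level OTU with a named reference;
* **genus_match** — shares a genus-level OTU with named references *and*
  is within the genus's empirical bound of every named member of that OTU;
* **unidentified** — otherwise, with a *borderline* flag when the nearest
  reference lies in (0.24%, 0.27%].

Unidentified OTUs receive deterministic environmental-barcode labels
(`EB<genus-number>-<species-number>`), or family-level labels when they
share a genus OTU with a designated family anchor strain.

## Trees and ordination

**Neighbor joining** (Saitou–Nei, Studier–Keppler Q criterion) over the
percent PWD matrix, used as a clustering visualisation rather than a
phylogeny. Negative branch lengths are clamped to zero with the deficit
moved to the sibling branch, preserving the joined pair's path length; on
additive matrices leaf-to-leaf path lengths reproduce the input exactly.
Ties are broken by the smallest leaf-label pair. One numerical subtlety:
the Q matrix is not bitwise symmetric (the two triangles subtract in
different orders in floating point), so the minimum is searched over the
upper triangle only. The Newick writer is iterative to tolerate deep,
unbalanced join orders on survey-sized trees.

**PCoA.** Distances (optionally standardised by the standard deviation of
all off-diagonal entries) are squared, Gower double-centered and
eigendecomposed. Only positive-eigenvalue axes are kept; p-distance
matrices are generally non-Euclidean, and the negative axes are dropped and
counted rather than corrected.

## Synthetic data generator

The generator plants structure whose recovery is provable, not merely
likely:

* At barcode length 430, one mismatch is 0.2326% (inside the 0.24% species
  cut-off) and six mismatches are 1.395% (inside the 1.4% genus bound).
  Species are therefore planted as cliques of diameter ≤ 1 mismatch
  separated by ≥ 2 mismatches; genus clusters have diameter ≤ 6 and
  separation ≥ 7. A post-generation verifier recomputes the full mismatch
  matrix and fails loudly if any planted constraint is violated, so a
  generated dataset is a certificate of its own ground truth.
* Substitutions are placed at explicitly allocated, disjoint sites and are
  stop-safe (never creating an in-frame stop). Variant records re-use an
  already-substituted site with a different non-ancestral base, so a
  species clique never collapses toward its genus anchor.
* Pseudogenes are planted as minimal substitutions to a stop codon;
  editing-site stops are planted in all strains of one species so the
  shared-stop inference is exercised.
* Paralogous strains receive clone libraries with two copy classes a fixed
  number of mismatches apart.
* The survey-scale profile (`paper_scale_profile`) plants the full
  structure of a realistic study: 336 reference strains (189 named,
  including identical-sequence species pairs, clade-organised genera, a
  paraphyletic genus and deep intra-genus splits), 713 environmental clones
  collapsing to 603 uniques in 531 species-level OTUs, 51 species-linked
  and 30 genus-linked uniques, a family-scale expansion around an unnamed
  anchor strain (177/122/26 clone counts), one paralogous strain, and
  site/depth/season metadata. All counts are seed-invariant.

## Limitations

* Sequences are assumed 5'-aligned (fixed primers); there is no aligner.
* No chimera detection.
* The generator does not model indels, rate heterogeneity or selection —
  it optimises for exact, verifiable geometry rather than realism of the
  substitution process.
* NJ trees over p-distances are clustergrams; no bootstrap support is
  computed.
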