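# Methods

This note documents the models and procedures implemented in `genefam`,
the parameters that matter, the numerical choices, and what the
synthetic-data validation does and does not establish.

## Domain scan

The scanner operationalizes the bZIP architecture directly: an invariant
asparagine with an arginine or lysine eight residues downstream
(N-x7-R/K) marks the basic region, and a leucine zipper is the longest
arithmetic run of period 7 starting within `zipper_search_window`
(default 60 aa) downstream of the anchor. Each run position must hold L
or a residue from `hydrophobic_set` (default {I, V, M, F}), with at most
`max_mismatch_heptads` (default 1) non-leucines per run; `X` and gap
characters never match. A protein is a family member when the best run
reaches `min_heptads` (default 3); an anchor with a shorter (or no) run
is reported as an *incomplete* domain for audit rather than silently
dropped, since real surveys use exactly this distinction to exclude
borderline loci. Overlapping anchors are resolved by maximal zipper
length, ties to the leftmost anchor. The span from the anchor to the
last heptad is annotated against the canonical 40–80 aa domain window
as a soft flag, not a filter. `min_heptads = 3` and the hydrophobic set
are calibration choices of this package (the architecture description
does not fix them) and are exposed in `ScanConfig`.

## Gene models and structure

GFF3 is consumed via `gffutils` (gene/mRNA/exon/CDS only; other feature
types logged and ignored). A gene with several transcripts collapses to
the one with the longest summed CDS, falling back to summed exon length
— a survey reports one CDS per locus. Intron statistics prefer CDS
segments when the annotation provides them (introns *in open reading
frames*), falling back to exons, and each record notes which source was
used; intron length between consecutive segments is
`next.start − prev.end − 1`. Percentages in distribution tables round
half-up to integers, matching the integer-percent presentation such
tables conventionally use. Genes that cannot be anchored to a
chromosome are modeled on a reserved `chrUn` pseudo-chromosome: they
keep ordinals for bookkeeping but are excluded from tandem and synteny
calls and reported as an `unanchored` row in distributions.

## Alignment and phylogeny

Pairwise protein alignment is global with affine gaps (BLOSUM62, open
10, extend 0.5 — ClustalW-like defaults), delegated to Biopython's
`PairwiseAligner`; a gap of length k costs open + (k−1)·extend.
Progressive multiple alignment merges profiles in neighbor-joining
order over 1 − identity distances; profile–profile alignment scores a
column pair by the expected BLOSUM score of its residue frequency
vectors (gaps carry zero weight) with the same affine penalties, and
the traceback prefers match over gap deterministically, so the MSA is a
pure function of the input.

Distances from the MSA are p-distances with pairwise gap deletion
(complete deletion available), Poisson-corrected by default
(d = −ln(1 − p)); a saturated pair (p = 1) receives a fixed ceiling of
10 substitutions/site with a warning rather than an infinity.
Neighbor joining is the standard Saitou–Nei agglomeration on the
Q-criterion with ties broken to the lowest node-index pair (required
for determinism), and negative branch lengths are clamped to zero with
the deficit transferred to the sibling branch (the common
MEGA/ape behavior). On exactly additive distances this recovers the
generating topology and branch lengths to numerical precision, which
the test suite verifies on random 5–8 leaf trees.

Bootstrap replicate r draws its resampled columns from a stream seeded
by (seed, r), so supports are reproducible and do not depend on taxon
input order; support is the percentage of replicates whose NJ tree
contains each internal split of the full-data tree. All internal nodes
are annotated; no collapse threshold is applied.

Group assignment walks the splits around each query leaf from smallest
to largest and transfers the label of the smallest leaf set whose
references are non-empty and unanimous; equal-size candidate sets with
conflicting labels are treated as ambiguous and fall through to the
nearest reference by path length (exact ties: lexicographically smaller
label, flagged). With no reference leaves, everything is `unassigned`
with a warning.

## Duplications and synteny

Homology is operational, not curated: all protein pairs with identity
≥ `min_identity` (0.40) over mutual coverage ≥ `min_coverage` (0.60)
under the global alignment. A pair is **tandem** iff both genes share a
chromosome and `|ordinal_a − ordinal_b| − 1 ≤ 1`. Collinear blocks are
chained per chromosome pair by an O(n²) dynamic program over anchors
(both orientations; ordinal gaps ≤ `max_gap` = 25 on both sides),
scored by anchor count for oracle simplicity; the best chain is removed
and chaining repeats (greedy by score), so every anchor belongs to at
most one block, and blocks below `min_anchors` = 3 are discarded. A
non-tandem pair anchoring any block is **segmental** — same-chromosome
blocks included, since intra-chromosomal duplicated regions do occur;
everything else is unclassified (pairs with 2–10 intervening genes are
deliberately *not* given a separate "proximal" category). Tandem takes
precedence when both rules match: one pair, one call. Cross-species
anchor pairs are not required to have both sides in the family — a
syntenic partner of a family gene may itself be from another family —
and ortholog topology classifies connected components of the bipartite
pair graph as 1:1, 1:many, many:1, many:many by side sizes.

The 0.40/0.60 thresholds and the chaining parameters are package
defaults in the spirit of collinearity databases; all are
config-exposed.

## Ka/Ks (NG86 + Jukes–Cantor)

Codon alignments are built by threading each CDS onto its aligned
protein row (gap → `---`, terminal stop stripped, any
translation/length mismatch is an error naming row and column). Site
counts per codon are fractional: each position contributes the fraction
of its three single-nucleotide changes that are synonymous; changes to
stops count as nonsynonymous; s + n = 3 exactly. Differences between
codons average synonymous/nonsynonymous step counts over all orderings
of the differing positions, excluding pathways through stop codons and
renormalizing over the valid ones (if every pathway is blocked, all are
used with stop-adjacent steps counted nonsynonymous). Gap or ambiguous
codon columns are dropped pairwise. Site totals S, N are the mean of
the two sequences' counts; pS = Sd/S and pN = Nd/N are corrected by
d = −(3/4)·ln(1 − (4/3)p), undefined (NaN, flagged) at p ≥ 0.75; the
ratio is undefined when Ks = 0. Classification: > 1 positive, = 1
(within 1e−9) neutral, < 1 purifying.

The estimation method is this package's choice: the workflow it
reimplements names only the codon *aligner*, so published ratios from
such surveys (e.g. a maximum of 0.3082 across ortholog pairs) should be
expected to reproduce approximately, not exactly, under NG86.
Transition/transversion weighting and ML codon models are out of scope.

## Expression (ΔΔCt)

ΔCt = Ct(target) − Ct(reference) per sample on replicate pairs
(falling back to the reference replicate mean when replicate structures
differ); ΔΔCt = mean ΔCt(treated) − mean ΔCt(control);
fold = 2^(−ΔΔCt), i.e. amplification efficiency is fixed at 2.0 — no
efficiency correction is applied, matching instrument "normalized
expression" output when no standard curve is supplied. Replicate spread
is the pooled SD of per-replicate ΔCt and is reported as the fold range
[2^(−ΔΔCt−sd), 2^(−ΔΔCt+sd)] because "mean ± SD" is ambiguous between
the Ct and fold scales. Significance is a two-sided Student t-test on
replicate ΔCt (Welch by flag), starred at P < 0.05 / P < 0.01; no
multiple-testing correction across genes.

## Synthetic genomes

The generator realizes the survey's study conditions at desk scale, one
RNG stream from a single seed (identical seeds give byte-identical
files). Defaults: 5 chromosomes × 25 background genes; a family of 10
founders over five groups (A, D, F, I, S), each group grown from a
distinct random seed protein carrying a planted basic region and a
five-heptad zipper, members mutated at 8% per site outside the domain;
an intronless share of 23/112 (the canonical value for this family
size in the surveyed genome, realized as an exact count); two tandem
events (0 and 1 intervening genes) and one 4-gene segmental block;
duplicate pairs diverged at ω = 0.2 and t = 0.3 expected proposed
mutations per codon (moderate divergence). Background genes are random
ORFs rejection-sampled so none carries a complete bZIP domain. Coding
evolution is an acceptance–rejection scheme: synonymous proposals are
always accepted, nonsynonymous with probability ω (for ω > 1 the
complementary scheme must be enabled explicitly), stops rejected;
because proposals are uniform over single-nucleotide changes — the same
weighting NG86 uses for sites — the realized dN/dS tracks ω, and the
calibration is itself a test (mean NG86 ratio within ±0.05 of ω over 50
pairs of 600 codons). Planted domains are frozen during duplicate
divergence so family membership survives the mutation load.

What the generator does *not* emulate: intergenic repeats and isochore
structure, indels in non-coding DNA, transposable elements,
whole-genome duplication, UTRs (gene exons are coding), codon-usage
bias, and alignment ambiguity from long indels. Passing recovery tests
therefore demonstrate the correctness of the positional logic, the
scanner, the chaining, and the estimators under clean, separable
conditions — not robustness to the full messiness of real annotations.
For duplication-recovery checks the family uses one founder lineage per
group, so that every homologous pair traces to exactly one planted
event; the default family (two founders per group) exercises the scan,
structure, and phylogeny surfaces where within-group homology is
expected and harmless.

## Problem sizes

The shipped analyses and the acceptance script run at desk scale: ~130
genes per genome, 8–13 family members, 100 bootstrap replicates (the
conventional 1000 is one flag away), 50 replicate pairs × 600 codons
per ω in the Ka/Ks calibration, 200 random trees for the NJ check.
These sizes were chosen so the full validation runs in minutes on one
CPU while keeping every estimate's Monte-Carlo error well inside the
stated tolerances.

## Known limitations

- The progressive MSA is a straightforward profile merger without
  iterative refinement; deep families with long indels will align worse
  than dedicated tools.
- NG86 saturates near p = 0.75 and is mildly downward-biased at higher
  ω (visible as 0.47 recovered at planted 0.5); ML codon models are out
  of scope.
- The chainer scores blocks by anchor count; similarity-weighted
  scoring is available behind a flag but not used by default.
- Tandem calls depend on annotation completeness: unannotated
  intervening genes change ordinal gaps.
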