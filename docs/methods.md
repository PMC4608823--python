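# Methods

This note documents the models, estimators and design choices behind
barcode-librarian, and what the synthetic-data tests do and do not
demonstrate about real libraries.

## Distance model

Pairwise distances use the Kimura 2-parameter model. For each pair,
comparable sites are those where both sequences carry an unambiguous
A/C/G/T (*pairwise deletion*); IUPAC ambiguity codes and gap/padding
characters are excluded rather than fractionally counted. With transition
proportion `P` (A↔G, C↔T) and transversion proportion `Q` over `n`
comparable sites,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).

Pairwise deletion is used because barcodes in a curated library are
typically trimmed to different extents (550–657 bp within a 658-column
alignment); complete deletion would discard most of the data. When either
log argument is non-positive (substitutional saturation) or `n = 0`, the
distance is flagged undefined and masked; it is never clamped to a large
constant, since a clamped value would silently distort pooled means and
threshold estimates. Pooled summaries ("mean intraspecific distance") are
means over all conspecific pairs, not means of species means; per-species
means are also reported, since the two differ whenever sampling is uneven.

## QC

A record passes QC iff its ungapped length strictly exceeds the minimum
(default 550 nt, the conventional cutoff for a "full" barcode) and its
best reading frame contains no stop codons under the invertebrate
mitochondrial code (NCBI table 5). The frame is the one among {0, 1, 2}
minimising the stop count, ties resolved toward frame 0; the library
format does not record frame, so inferring it this way is the only option
that never rejects a clean sequence.

## Haplotypes

Haplotype identity is exact string equality over the full alignment width,
with padding characters treated as ordinary mismatch-breaking symbols:
sequences trimmed to different extents are distinct haplotypes even when
they agree on all shared columns. This is deliberately conservative — the
alternative (identity over the shared extent) can chain non-identical
sequences into one haplotype through a short intermediate. Collapsing is
per-species by default; global scope exposes haplotypes shared across
species labels.

## Barcode gap and best-compromise threshold

For a pool of intraspecific distances and a pool of
congeneric-interspecific distances, the threshold objective is the
unweighted sum of the two cumulative error proportions

    total_error(t) = Pr(intra > t) + Pr(inter <= t),

i.e. conspecific pairs a cutoff `t` would fail to match plus
heterospecific congeneric pairs it would wrongly match. A distance exactly
equal to `t` counts as a match; relative weights of the two error types
are configurable but default to 1:1. The objective is a step function
changing only at observed distances, so the candidate grid of observed
values plus midpoints is exhaustive. When the minimum is attained on an
interval — always the case under a true gap — the reported `t*` is the
interval midpoint, and the interval itself is reported alongside (for a
gap group, its endpoints are the gap bounds). A *true barcode gap* is
declared when the intraspecific maximum lies strictly below the
congeneric-interspecific minimum; both extremes are reported either way.

## Best Match / Best Close Match

Identification is leave-one-out: each query is matched against every other
record (outgroup excluded). Best Match assigns the species of the
minimum-distance reference set: TP if all minimal references are
conspecific, FP if none are, ambiguous if the set spans several species.
Best Close Match additionally requires the best distance to lie at or
below a threshold; queries above it are set aside as FN (nearest reference
conspecific) or TN (heterospecific). Species with a single sequence are
excluded as queries — they can never self-match, so including them would
only depress success rates mechanically — but stay available as reference
candidates, which keeps the query-count arithmetic (queries = sequences −
singletons) transparent. Ties at the minimum use exact equality of
computed distances; an epsilon tolerance is exposed (default 0) because
tie behaviour in legacy tools is undocumented. Records can be excluded
from identification entirely (e.g. suspected mislabels) without removing
them from the library. BCM thresholds default to per-subfamily
best-compromise estimates with the dataset threshold as fallback; genus
thresholds vary too much in small genera to be a safe default.

## NJ tree and species clusters

Neighbor joining follows the classic agglomeration (Q-criterion,
rate-corrected split branch lengths, average reduction). Negative branch
lengths are clamped to zero with the deficit moved to the sister branch,
preserving path lengths; on additive inputs the output reproduces the
input matrix exactly (tested to 1e-9). Bootstrap support resamples
alignment columns uniformly with replacement, rebuilds the matrix and tree
per replicate, and scores each internal edge of the point tree by the
percentage of replicates containing the same unrooted bipartition; since
bipartitions are unrooted while node labels are not, the support map is
keyed by bipartition so rerooting cannot misattribute support. A replicate
whose resampled matrix contains an undefined distance is skipped without
shrinking the denominator (support is then conservative).

A species' *cluster count* is the minimal number of disjoint clades on the
outgroup-rooted tree whose leaf union is exactly that species' specimens
(equivalently, its maximal monochromatic clades). One cluster means the
species is monophyletic on the tree; for broken species the labels nested
inside the spanning clade are reported. An unrooted-bipartition variant of
"cluster" was considered and rejected as the default because the rooted
reading matches how reference trees are inspected in practice.

## Synthetic libraries

The simulator evolves sequences down a genus → species → individual
hierarchy under K80 with exact transition probabilities; K80 (uniform base
frequencies) is chosen over HKY to stay dual to the K2P estimator.
Expected pairwise K2P distance equals genealogical path length, so pool
means are predictable from the configured depths: intraspecific
2·depth_individual, congeneric 2·(depth_species + depth_individual).
Branch lengths are fixed per level (no rate jitter) to keep expected-value
tests sharp. The root is drawn codon-wise from sense codons and lineages
evolve with stop codons suppressed (a codon mutating into TAA/TAG is
re-evolved from its ancestral state), mimicking purifying selection on a
coding fragment; the conditioning excludes 2 of 64 codon states and biases
expected divergence negligibly. No indels are simulated; ragged ends can
be emulated by terminal truncation.

Default parameters are the study conditions of a curated hoverfly COI
library: 26 genera, 4 species per genus (~100 nominal species), 658 bp,
singleton fraction 32/98, non-singleton species of 2 + Poisson(5.4)
specimens (~550 barcodes in total), kappa 3 (a typical COI transition
bias), depth_individual 0.0035 and depth_species 0.0315 so that pooled
intraspecific ≈ 0.007 and congeneric ≈ 0.07, depth_genus 0.045, and an
outgroup at depth 0.2. Scenarios inject the pathologies such libraries
show: `twin_pair` (two species labels at divergence 1e-4, the
recently-diverged-pair situation), `cryptic_split` (one label spanning two
species-depth clades), `shared_haplotype` (one sequence copied across two
labels in a genus), `singleton_burst` (the singleton fraction above).

What passing synthetic tests show — and what they do not: the simulator
produces homogeneous rates across sites and lineages, uniform base
composition, no indels and no sampling structure beyond the three-level
hierarchy, so success on simulated libraries demonstrates correctness of
the estimators and bookkeeping, not robustness to rate heterogeneity,
composition bias or geographically structured intraspecific variation in
real data.

## Numerical and procedural choices

- Distances of exactly 0 are stored as +0.0; undefined entries as NaN with
  a mask accessor.
- NJ tie-breaks at the Q-minimum take the first index pair in row-major
  order, making trees deterministic for given input order; leaf
  permutation invariance is tested on the split sets.
- Thresholds, gap bounds and distances are reported in substitutions/site;
  percentages are percentages of the stated denominator (`n` in the
  acceptance output).
- The acceptance script runs the full evaluation at the default study
  scale (~560 barcodes) with 100 bootstrap replicates — enough for stable
  ~1%-resolution support values while keeping a from-scratch rerun at a
  few minutes; analysis drivers accept `--bootstrap` for heavier runs.
- All randomness flows through `numpy.random.default_rng` seeded from the
  caller; identical configs give byte-identical FASTA/TSV outputs.

## Known limitations

- Only the K2P distance is implemented (no JC69/TN93/GTR); the evaluation
  pipeline is distance-model-agnostic in structure but not in code.
- Maximum-likelihood tree inference and model selection are out of scope;
  cluster assessment is defined on the NJ tree.
- XLSX metadata is not ingested; export to TSV/CSV first.
- The best-compromise threshold is a population summary of the library at
  hand; it is not an identification error-rate guarantee for queries drawn
  from outside the library's taxon or geographic coverage.
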