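# Methods

## Mutual-information estimation

Association between expression vectors is measured by a spline-smoothed
histogram estimator.  Each vector is rescaled to [0, 1] by min–max (a
rank-based rescaling is available behind `MIConfig.rescale="rank"`), and each
observation receives fractional membership in B = 6 bins through the B-spline
basis of order s = 3 on an open uniform knot vector; order 1 recovers plain
indicator binning.  Rows of the weight matrix sum to one exactly (partition
of unity), marginal bin probabilities are per-bin mean weights, joint
probabilities come from per-observation outer products, and entropies are in
bits.

Raw MI is `H(X) + H(Y) − H(X,Y)`.  **Normalization** divides by
`min(I(x,x), I(y,y))`, the self-MI of the less informative variable.  Under
indicator binning the self-MI equals the marginal entropy, so this reduces to
the textbook `raw / min(H(X), H(Y))`; with smoothing orders s > 1 the outer
product of a weight row with itself puts mass off the joint diagonal, so
`I(x,x) < H(X)` and the self-MI — not the entropy — is the attainable
maximum.  Dividing by it is the only choice that keeps the score in [0, 1]
with `I(x,x) = 1` at every order.  Scores for negatively Pearson-correlated
pairs are clipped to zero by default (the analysis concerns co-expression;
a signed variant exists behind `clip_negative=False`).  Zero-variance inputs
score 0 rather than NaN.  Entropy sums run over sorted probabilities so that
MI is exactly symmetric in floating point.

## Attractor metagenes

Starting from a seed gene's (log-normalized) expression vector, each
iteration scores every gene by normalized clipped MI with the current
metagene, raises the scores to exponent *a* (3 for UMI, 5 for full-length or
bulk, chosen automatically from the matrix modality and overridable),
normalizes them to sum to one, and replaces the metagene with the weighted
average expression profile.  Convergence is declared when the L∞ change of
the full MI vector drops below 1e-4 (no tolerance is canonical for this
family; 1e-4 changes rankings by at most the noise floor).  Non-convergence
within 100 iterations returns a flagged result with the delta trace rather
than raising, so cohort loops proceed.  A converged attractor whose
second-ranked score falls below 0.2 is flagged `degenerate`: the iteration
collapsed onto the seed alone, the signature of a matrix without any
co-expression structure around the seed.  Ranks are 1-based; ties in the
final ranking break lexicographically.

The consensus variant iterates one shared gene-weight vector over several
datasets restricted to their common gene universe.  Each dataset forms its
own metagene from the shared weights (per-dataset metagenes, since pooling
expression across differently scaled datasets is not meaningful), computes
its own MI vector, and the vectors are combined by **weighted median** with
weights `log(n_units)` before exponentiation.  The lower weighted median is
used (smallest value whose cumulative weight reaches half the total), a
deterministic and slightly conservative convention: with two datasets it
takes the smaller value, so private structure in one dataset cannot carry
the consensus.

## Overlap statistics

The null model for gene-list overlap is uniform random sets of fixed sizes
from a finite universe.  For two sets the overlap is hypergeometric; the
upper tail is summed from log-pmf terms rather than taken from a survival
function so that P-values of order 1e-33 and far smaller retain relative
accuracy.  For n sets, the common intersection size is built by chaining
hypergeometric conditionals — given that the first i−1 sets share j
elements, that intersection is a uniform j-subset, so intersecting with the
next set is `Hypergeom(N, j, m_i)` — with the convolution performed on log
probabilities.  The chain is verified in the tests against exhaustive
bitmask enumeration for universes up to 12 and against a vectorized
Monte-Carlo oracle (200,000 draws) at moderate P.  Universe conventions:
within one matrix, the number of genes analyzed; across studies, 20,000.

## Differential expression

Two-sided Wilcoxon rank-sum per gene on log-normalized values, exact when
both groups have ≤ 25 tie-free observations and a tie-corrected normal
approximation with continuity correction otherwise.  Fold change uses the
de-logged means with pseudo-count 1:
`logFC = log((mean(expm1 A)+1)/(mean(expm1 B)+1))` (natural log), the
convention that makes the |logFC| > 0.25 threshold meaningful on
log-normalized data; the pseudo-count itself is a convention, flagged here.
Significance requires |logFC| strictly greater than 0.25 **and** Bonferroni
adjusted P < 0.1.  Up- and down-lists are ranked by |logFC|.

## The pan-cancer screen

Per cancer type: genes with more than 50 % zero-count samples are removed;
log2(count+1) values are quantile-normalized across samples using the mean
of order statistics as the reference distribution, tied entries sharing the
mean of their positions' reference values (so the exact
identical-sorted-vector property holds on tie-free data and approximately
under ties); protein-coding genes are ranked by MI with *COL11A1* and the
type is excluded unless *THBS2* or *INHBA* ranks in the top 50; lncRNAs and
miRNAs are then ranked in the surviving types and sorted by median rank
(ties by mean rank).  Biotype is an input annotation column; no external
annotation resource is consulted.

## Synthetic cohorts

The generator encodes the transition the pipeline is meant to recover.  Each
fibroblast carries a latent coordinate t ∈ [0, 1]; gene programs respond to
t through logistic curves (decreasing ASC, midpoint 0.35; increasing CAF,
midpoint 0.55, steepness 8) or a Gaussian bump (transient *SFRP4*/*RARRES1*,
peak 0.5, width 0.15); pan-fibroblast markers are constant; *COL11A1*'s
midpoint is shifted +0.25 so it is the last CAF gene to switch on.  Counts
are negative-binomial (shared dispersion 0.3, the standard scRNA-seq count
model) around `library_factor × amplitude × shape(t)`, with a log-normal
per-cell depth factor (median 12, giving cell totals of a few thousand
counts).  Program genes outside their own compartment sit at a small ambient
level (0.005 relative units) identical across compartments, so "off" genes
yield rare stray counts with no structure.  Per-gene amplitude multipliers
reflect expression prominence: *APOD* ×2.5 and *CFD* ×1.8 (among the most
abundant ASC transcripts), *COL11A1* ×2.0 (one of the most strongly induced
CAF collagens).  Background genes span amplitudes 0.01–4 on a log grid —
from near-silent to abundant — in every compartment.

Sample presets: normal samples put fibroblast t at 0 with jitter
(sd 0.03); tumor samples draw t uniformly from a window around the stage
mean (half-width 0.3, narrowing near the endpoints, since samples that have
barely started or essentially completed the transition are dominated by
homogeneous fibroblasts).  Pericyte and epithelial compartments express
their own constant marker programs so cell identification is non-trivial.
Bulk cohorts for the screen add a per-sample stromal-content factor
co-scaling *COL11A1* with a block of background genes in every type, a
stronger CAF-abundance factor co-scaling *COL11A1*/*THBS2*/*INHBA* and one
planted lncRNA (`LNC-CAF1`) in positive types only, and a zero-inflated gene
slice to exercise the 50 %-zeros filter.

What the generator does **not** emulate: doublets, batch effects, ambient
RNA contamination, realistic transcriptome size (tests use 60–300 background
genes, not 20,000), UMI saturation, or cell-cycle structure.  Passing tests
therefore demonstrate the algorithms recover planted structure under NB
noise and compartment mixtures, not performance on any real accession.

## Cell identification

Graph-based clustering is out of scope; cells are typed by marker scores:
mean log-normalized expression of *LUM*/*DCN*/*COL1A1* (fibroblast) vs
*RGS5*/*ACTA2*/*PDGFRB*/*ADIRF* (pericyte), calling the stronger class when
it exceeds 1.0 (configurable; chosen so that a single stray marker count in
a non-mesenchymal cell stays below threshold under the NB noise model).
The quality filter keeps cells whose best marker reaches log-normalized 3.0
(inclusive), applied per sample; samples with fewer than 20 fibroblast calls
(strict) are excluded.

## Problem sizes and determinism

The test suite and acceptance battery run on deliberately modest sizes:
~100–500-gene matrices with 300–600 mesenchymal cells per sample, 20
replicate cohorts for the ordering check, 6 bulk types × 150 samples for the
screen, 200,000-draw Monte-Carlo checks, and 2,000-gene DE calibrations —
sizes at which every planted effect is comfortably detectable and the whole
suite completes in about a minute.  All randomness flows through explicit
integer seeds (per-sample seeds derived from a master seed via
`SeedSequence.spawn`); the attractor iteration itself contains no
randomness, and re-running the pipeline with an identical configuration
reproduces its report byte-for-byte.

## Known limitations

- The MI estimator is not bias-corrected; with few observations (bulk types
  with tens of samples) rankings among weakly associated genes are noisy.
  The screen presets therefore use ≥ 150 samples per type.
- The ordering comparator (APOD rank) saturates once samples are dominated
  by fully transitioned CAFs: among several such samples the recovered
  order is essentially arbitrary, which bounds the achievable rank
  correlation in cohorts with many late samples.
- The consensus' lower weighted median is conservative with two datasets;
  with three or more it behaves as a true median.
- `quality_filter` and marker typing assume the marker genes are present in
  the matrix; missing markers are logged and skipped, and only an entirely
  absent marker panel is an error.
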