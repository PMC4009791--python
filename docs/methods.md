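# Methods

This note documents the models, algorithms and numerical choices behind
`somportraits`, the assumptions they rest on, and the limits of what the
synthetic-data tests demonstrate.

## Preprocessing

Samples are quantile-normalized onto the mean empirical distribution (the
across-sample mean of order statistics). Tied values within a sample receive
the mean of the reference quantiles over their rank span; this keeps the
transform symmetric under column permutations and makes it idempotent.
Values are then log10-transformed and each gene is centered on its cohort
mean, yielding the log fold change Δe. The order is fixed
(quantile → log10 → center); matrices must be complete and strictly
positive — missing or non-positive cells are rejected rather than imputed,
because imputation would corrupt the percentile statistics used downstream.

## SOM training

Genes are points in sample space; a rows × cols grid of metagene weight
vectors is fitted with the online SOM rule under a Gaussian neighborhood
on the rectangular grid (Euclidean grid metric, 4-connectivity convention
downstream). Parameters, with defaults:

| parameter          | default                      | role |
|--------------------|------------------------------|------|
| rows × cols        | 50 × 50 (20 × 20 in examples)| grid resolution; choose K well below the gene count |
| epochs             | 10                           | each gene presented ten times |
| initial radius     | max(rows, cols)/2            | neighborhood σ at step 0 (grid units) |
| final radius       | 1                            | σ at the last step; linear decay per step |
| learning rate      | 0.05 → 0.005                 | linear decay per step |
| init               | `linear`                     | grid seeded on the plane of the two leading principal directions (±2 SD), longer grid axis on PC1; `random` fallback |
| seed               | 0                            | presentation order (shuffled per epoch) and fallbacks |

Component signs in the PCA initialization are fixed (largest-magnitude
loading positive) so training is fully deterministic given the seed.

After the scheduled epochs, one zero-radius batch step replaces every
populated metagene by the exact centroid of its assigned genes (empty
metagenes keep their weights) and the assignment is recomputed. Rationale:
the analysis stack interprets metagenes as cluster averages (spot profiles,
mean portraits, prototypes), and the centroid step makes this exact — a 1×1
map equals the global mean profile, and because genes are row-centered,
every mean portrait over all samples is exactly zero — while leaving the
learned topology intact. The quantization error (mean Euclidean distance of
genes to their best-matching metagene) is recorded before training, at each
epoch boundary, and after the centroid step; it decreases monotonically
from the first epoch boundary onward. The value *at initialization* can be
lower than after the first epoch, because the PCA plane is already close to
the data while early large-radius epochs smooth the map toward the grand
mean; monotonicity is therefore a property of epoch boundaries, not of the
init.

Portraits are rendered with a per-sample color anchor at the 10th/90th
percentiles of the portrait's own values, so the deepest blue/red always
mark that sample's strongest under-/over-expression.

## Spot modules

Per sample, the over-expression mask keeps tiles at or above the sample's
98th percentile (under: at or below the 2nd). All masks are transferred to
one summary map which keeps, on the union of selected tiles, the strongest
metadata value across samples (max for over, min for under) and is neutral
(0) elsewhere. Global spots are the 4-connected components of the
non-neutral tiles; 4-connectivity is the strictest reading of "disjoint
region" and prevents diagonal bridging. We deliberately do **not** re-cut
the summary map at a second 98th-percentile threshold: every non-neutral
tile already passed the per-sample percentile criterion, and cascading a
second 2% cut empirically shrinks spots to one or two tiles and destroys
module recovery. A `secondary_percentile` option restores the stricter
behavior for users who want spot cores only. Spots are labeled A, B, …
sorted row-major by centroid, a convention chosen purely for determinism.
Member genes of a spot are the genes whose best-matching metagene lies in
it. Note that with a P-percentile criterion a grid of K tiles yields
⌈(1−P/100)·K⌉ tiles per sample mask; on very small grids (≤ ~100 tiles) the
98th percentile keeps only one or two tiles, and a scale-appropriate lower
percentile (e.g., 95) resolves modules better.

## Enrichment

Overrepresentation of a gene set in a spot is the right-tailed
hypergeometric probability of at least the observed overlap, with the
universe restricted to the genes present in the analyzed matrix. Screening
across a collection applies the Bonferroni threshold α/n with a strict
inequality (p < α/n); with α = 0.05 and n = 5,000 sets this is the familiar
10⁻⁵ cut. Bonferroni is conservative for overlapping gene sets; the
threshold is a lower bound on acceptable sets, not a calibrated error rate.

The gene set Z-score of set *S* in sample *m* is

    GSZ_m = (⟨Δe⟩_S,m − ⟨Δe⟩_all,m) / SE_m,
    SE_m = s_m · sqrt(1/n_S − 1/N),

with s_m the standard deviation (ddof = 1) of all N gene values in sample
*m*. SE_m is the exact standard error of the mean of n_S values drawn
without replacement from the N values of the sample, so under random set
membership GSZ has mean 0 and variance 1 — the property the calibration
tests verify (5,000 draws: mean within ±0.05, variance within ±0.1). The
estimator is the finite-population choice among several plausible
"standard error" readings and is deliberately isolated in one place.

Population maps count set members per tile; members absent from the matrix
are reported, never errors.

## Sample similarity

All similarity analyses run on the metadata (K values per sample), which
denoises comparisons relative to the raw gene space. Pearson correlation
yields the pairwise correlation map; the correlation network connects pairs
with r strictly above the threshold (default 0.5) and is laid out by a
seeded force-directed embedding weighted by r. Neighbor joining uses the
standard Q-criterion with ties broken toward the lowest index pair;
negative branch lengths are clamped to zero and recorded. For additive
distances the tree reproduces the input path lengths exactly (verified
against both a brute-force oracle and an independent implementation). ICA
(FastICA) embeds samples on two components; since ICA is defined only up to
permutation and sign, components are ordered by decreasing excess kurtosis
and signed so their skewness is non-negative.

## Subtyping

A spot's prototype is an artificial portrait carrying the global metadata
maximum on the spot's metagenes and zero elsewhere. k-means (Lloyd) runs
from these prototypes with positional cluster identity, so clusters inherit
spot labels and no matching step is needed. The recorded objective
(within-cluster sum of squares at assignment time) is non-increasing; an
emptied cluster is re-seeded with the point farthest from its centroid.
Convergence: unchanged assignment and objective change below `tol`
(default 10⁻⁹), capped at `max_iter` (100).

Bootstrap stability subsamples 80% of the cohort without replacement
(default 500 repetitions), runs k-means initialized at the subtypes' mean
meta-states within the subsample, and scores each sample by the fraction of
draws in which it lands in its designated class; repetitions missing a
class entirely are discarded and counted. Two caveats discovered while
validating the score and worth knowing when interpreting it: (i) on cleanly
separated clusters every labeling consistent with the geometry scores 1.0 —
the score discriminates only when samples sit near decision boundaries, and
(ii) a sample exactly midway between two clusters scores ≈ 0.5 only under
exact symmetry; in any finite dataset the realized asymmetry of the cluster
means usually exceeds the per-resample jitter and pins such a sample's
score near 0 or 1.

Consensus clustering subsamples 80% of the samples (default 500
repetitions) per class number k, cuts an average-linkage hierarchical
clustering on Euclidean metadata distances at k, and accumulates
co-clustering frequencies normalized by co-drawing counts. The CDF of the
upper-triangle consensus values summarizes each k; the relative gain in CDF
area from k−1 to k collapses once k exceeds the intrinsic class number.
Class-number assessment is run on corrected (contamination-free) data:
a planted contamination signature otherwise claims an early hierarchical
cut and blurs the elbow. Subsample fractions and repetition counts follow
the common consensus-clustering convention and are exposed as parameters.

## Phenotype and survival statistics

Fisher's exact test for r×c tables uses the probability-ordering two-sided
definition: the sum of probabilities of all margin-fixed tables whose
multivariate hypergeometric probability does not exceed the observed one
(with a 10⁻⁷ relative guard against floating-point ties, as in standard
implementations). Tables with (r−1)(c−1) ≤ 6 free cells are enumerated
exhaustively — 2×c tables through a vectorized column factorization, others
recursively; larger tables fall back to seeded Patefield Monte Carlo
sampling with an add-one estimator and reported standard error. The exact
path agrees with R's `fisher.test` to full precision on 2×2 through 3×3
spot checks and with a rational-arithmetic enumeration oracle in the test
suite. Characteristic tables drop missing phenotype entries per
characteristic (not listwise) and report percentages of the full cohort.

Kaplan-Meier estimation and the unstratified log-rank test (chi-square with
groups − 1 degrees of freedom, standard hypergeometric variance, no extra
tie correction) are delegated to lifelines. Calibration: over 10,000 null
simulations (exponential times, two groups of 50, no censoring) the
rejection rate at nominal 0.05 lies within [0.04, 0.06].

## Synthetic cohorts

The generator emulates the study design the framework targets. Defaults —
the package's reference conditions — are 2,000 genes × 120 samples, four
subtypes at prevalences 28/19/20/33% (largest-remainder rounding, ties by
class order, so 221 samples give 62/42/44/73), two antagonistic main
modules (5% of genes each, ±1.0 log10 units in the two main classes), two
intermediate modules (4% of genes, +1.0 in one intermediate class each), a
contamination signature (3% of genes, +1.5 in three samples spread across
classes), i.i.d. Gaussian noise of 0.3 log10 units, and per-class
exponential survival with medians 8/2.5/2.5/6 time units and 30%
censoring. Intensities are emitted as 10^(baseline + effects + noise) with
per-gene baselines log-uniform over 10¹–10³, so the real preprocessing path
is exercised. Module and contamination layouts scale proportionally when a
different cohort size is requested. Survival records are censored with
probability `censor_rate`, a censored record reporting a uniform time
before its event — exact in expectation, non-informative, and sensible at
`censor_rate` = 1.

What the generator does **not** emulate, and hence what passing tests do
not show about real data: the graded mBL↔non-mBL transition (here the
intermediate classes carry their own orthogonal modules rather than
intermediate levels of the main modules, so they neither bridge the main
clusters in the correlation network nor stress the bootstrap stability
score), probe-level microarray artifacts, batch effects, correlated noise
between genes outside the planted modules, and non-exponential hazards.
Because the planted classes are orthogonally separated, recovery results
(Jaccard ≥ 0.8, ARI ≥ 0.95) demonstrate correctness of the machinery, not
performance on weakly separated real cohorts.

## Problem sizes and determinism

Examples, tests and the acceptance script run the reference cohort at a
20×20 grid (400 metagenes for 2,000 genes), the package's own scaled-down
analog of a 50×50 grid for ~20,000 genes; recovery behavior is equivalent
and a full run takes minutes on a single core. One global seed fans out to
per-stage seeds via a stable hash of the stage name, so stage-level reruns
and full-pipeline reruns are byte-identical; all seeds stay below 2³¹.

## Known limitations

* Online SOM training is O(epochs · N · K · M); at full microarray scale
  (22k genes, 2,500 metagenes, hundreds of samples) a run takes hours on
  one core. Batch/minibatch training would help and is a natural extension.
* Spot segmentation has no sub-tile resolution: two modules mapped to
  adjacent tiles merge into one spot.
* The correlation-network layout is a visualization aid; edge lengths only
  approximately track correlation strength.
* Monte Carlo Fisher p-values are lower-bounded by 1/(reps + 1); very small
  p-values for large tables are reported at that resolution.
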