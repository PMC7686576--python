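# Methods

This note documents the statistical model, the synthetic cohort it is tested
against, and the numerical and design choices that were genuinely open.

## 1. Consensus peak atlas

Per-sample peak calls (BED, 0-based half-open) are first union-merged at
any-overlap *within* each sample, then pooled. A pooled candidate is *shared*
when peaks from at least `min_samples` (default 2) distinct samples overlap
it by at least one base; the 50% criterion applies only to the subsequent
merging step, not to sharing. Shared candidates are merged whenever the
pairwise overlap is at least `merge_frac` (default 0.5) of the **shorter**
peak — the fraction's denominator is not dictated by convention elsewhere,
and the shorter-interval reading is symmetric and the common dialect.
Merging runs as a left-to-right sweep over the sorted candidates, repeated
to a fixed point; because merging only extends right endpoints, the sweep is
deterministic and independent of sample order.

Two edge rules keep the atlas consistent with its contract
(non-overlapping intervals, support >= `min_samples`):

* pairs that still overlap after the fixed point (overlap below the merge
  threshold) are split at the midpoint of the overlapped run, left to right;
* support is recomputed on the final intervals, and split pieces that fall
  below `min_samples` are dropped.

Insertion counting assigns a single-base event at position *p* to the unique
atlas peak with `start <= p < end`; events outside all peaks or on unknown
chromosomes are ignored (the latter with a logged count). Strand is ignored
throughout.

## 2. Normalization, weights, donor correlation

* **log-CPM**: `log2((count + 0.5) / (libsize + 1) * 1e6)`; the half-count
  offset keeps zeros finite, the +1 keeps the scale exact for tiny libraries.
* **Observation weights**: an unweighted group-means fit yields per-feature
  residual SDs; the quarter-root SD is lowess-smoothed (span 0.5) against
  average log-count and the trend, evaluated at each observation's fitted
  log-count, enters as weight `trend^-4` (i.e. inverse predicted variance of
  log counts). The trend is floored at 1e-6 and extrapolated flat beyond the
  fitted range.
* **Sample quality weights**: an iterative moment scheme. At each step the
  weighted fit's standardized squared residuals are averaged per sample; the
  reciprocal updates the sample weight, which is clipped to [0.25, 4] and
  renormalized to geometric mean 1. Five iterations or convergence at 1e-4,
  whichever comes first. This deliberately replaces a REML estimator with a
  deterministic closed-loop estimator that is easy to test; for balanced
  designs the two agree closely in the cases that matter (a duplicated
  sample receives the same weight to within 5%).
* **Donor correlation**: repeated measures per donor are absorbed by one
  consensus correlation `rho` rather than per-feature mixed models. Per
  feature (the 500 highest-average features), the mean product of
  standardized residuals over same-donor pairs is divided by the mean
  squared residual; the per-feature correlations are Fisher-z averaged and
  transformed back. `rho` is 0 when no donor has two samples.

## 3. Moderated differential tests

Per feature, generalized least squares on the group-means design (one mean
per lineage x subset x age cell; 12 groups in the default design) with
block-equicorrelated errors: whitening by the inverse Cholesky factor of the
donor correlation matrix, then weighted least squares with the combined
(observation x sample) weights. Contrasts are linear combinations of group
means; the combined aging contrast sums the three per-subset old-minus-young
differences, so its estimate is exactly the sum of the per-subset estimates.

Residual variances are moderated by fitting a scaled inverse chi-square
prior via moments of log variances: `e_g = log s_g^2 - digamma(df/2) +
log(df/2)`; the excess variance of `e` over `trigamma(df/2)` is inverted
through the trigamma function (Newton, tolerance 1e-8, 50 iterations) to the
prior df `d0`, and the mean of `e` gives the prior variance `s0^2`. When the
log-variances are underdispersed the prior df is infinite and all variances
shrink to `s0^2` (logged). In the robust default, the prior is fitted on
variances winsorized at their 1st/99th percentiles so outlier features do
not inflate `d0`, but each feature's own unwinsorized variance is shrunk —
"robustness" lives in the hyperparameters, keeping the per-feature map
monotone. Moderated t uses `d0 + df` degrees of freedom (a large finite df
stands in for infinity). The moment-matching step reproduces the standard
Bioconductor implementation to ~1e-8 relative accuracy on shared input (see
the frozen cross-check in the test suite).

Benjamini–Hochberg adjustment is the literal step-up with capping at 1,
applied within each contrast.

GC-content (CQN) normalization of RNA counts is deliberately replaced by the
same log-CPM pathway — the synthetic data carry no GC covariate, and the
pipeline logs this as a deviation on every run.

## 4. Ordination and permutation inference

PCA centers features (no unit-variance scaling: features are selected by
variance, so variance semantics are kept) and decomposes by SVD; scores are
sample projections, loadings unit-norm, component signs fixed so the
largest-|loading| feature is positive. Defaults: top 5000 variable peaks
(ATAC), top 500 variable genes (RNA), top 500 |loading| features per
component for motif follow-up. Variance ties in feature selection break
lexicographically by id.

All permutation schemes operate on the donor, never the sample:

* **Paired lineage test**: per donor and stratum (subset x age), the CD8
  minus CD4 score difference; the statistic is the unweighted mean over
  strata of within-stratum donor means. A donor absent from a stratum (age
  strata only contain donors of that age) simply contributes nothing there.
  The null flips each donor's lineage labels as one unit.
* **Two-sample age test**: stratified by lineage x subset; statistic is the
  mean over strata of (mean old - mean young); the null reassigns age labels
  across donors, preserving group sizes. The old/young direction is fixed
  (old minus young); any other label pair is taken in sorted order unless an
  explicit order is given.
* **Trend test**: per stratum (lineage x age), Spearman correlation of score
  against the ordinal subset rank (naive=0 < CM=1 < EM=2), converted to
  `z = r * sqrt(n-1)` and combined over strata by Stouffer with equal
  weights (the equal weighting is a recorded choice; stratum sizes are equal
  in the intended design anyway). The null permutes subset labels within
  each donor(-lineage) block. Constant strata contribute z = 0 with a log
  notice.

Enumeration is exhaustive when the arrangement count is at most 20,000
(sign-flips: 2^donors; relabellings: C(n, n_old); trend: product of block
factorials); otherwise 10,000 Monte-Carlo draws with add-one smoothing
`p = (b+1)/(m+1)`, so p is never 0. Two-sided tests compare |statistic| with
a 1e-12 tolerance against ties.

The ordering probability of a prespecified complete order of g group means
is 1/g! under exchangeability; ties are an error rather than a convention.

## 5. Clustering and motif analysis

Sites are clustered on row-z-scored values (population SD; constant rows map
to zero) so the partition follows the heat-map geometry; the lineage
fold-difference comparison clusters raw per-subset log2 fold changes
(default k = 4). k selection uses the gap statistic: within-cluster
dispersion W_k (k-means inertia; for k = 1, total SS about the mean) against
B = 50 reference datasets uniform on the per-dimension min–max box;
`gap(k) = mean_b log W_k(ref) - log W_k`, `s(k) = sd_b * sqrt(1 + 1/B)`, and
the chosen k is the smallest with `gap(k) >= gap(k+1) - s(k+1)` (falling
back to the largest k). k-means is k-means++ with 25 restarts (10 inside the
gap search), deterministic given the seed.

Motif occurrences are inputs (annotation tables), not PWM scans. Enrichment
of a foreground peak set against a disjoint background is the one-sided
hypergeometric tail on the annotated universe — exact and oracle-checkable,
rather than a binomial approximation. Family reduction keeps the smallest-p
member per family (ties by motif id). Motif intensity is the per-group
z-score of the median (over motif-bearing peaks) of group-mean normalized
accessibility; the "median over peaks of group means" reading of this
ambiguous quantity is isolated in this single function.

## 6. Gene annotation and gene sets

A peak maps to the gene with the nearest TSS: distance 0 when the TSS lies
inside the peak, otherwise the base-pair gap to the nearest peak edge
(`max(0, start - tss, tss - end)`); ties go to the smallest gene id. The cap
is `max_dist` = 10 kb by default and `inf` reproduces an uncapped
closest-gene rule — both behaviours are used in practice and the cap is a
per-call argument, not a global.

Term enrichment reports both the one-sided Fisher exact p and the EASE
score: the same tail with the overlap decremented by one (floor at zero), so
single-gene overlaps can never drive a term. Enrichment is flagged at
EASE < 0.1; a BH-adjusted EASE column is included. Gene-set shifts in
per-gene fold differences use the Wilcoxon rank-sum test of set versus all
other genes — exact enumeration when the pooled n is at most 12 and tie-free,
otherwise the normal approximation with tie correction.

## 7. The synthetic cohort

The generator emulates the study design the analysis assumes: 6 young and 4
old donors, each contributing one sample per lineage x subset (60 samples,
12 groups), on a 10-Mb single-chromosome toy genome with 2000 non-overlapping
peaks (widths 300–800 bp, gaps >= 200 bp).

Planted structure, all on the log2 scale:

| class                | default share | effect |
|----------------------|---------------|--------|
| differentiation_up/down | 20% (split) | +/- 2.0 x rank/(n_ranks-1); old samples advance by `diff_age_coupling` = 0.25 of a rank step |
| age_up               | shared        | +1.5 in old, both lineages (bZIP/Tbox labels) |
| age_down_cd8         | ~8.5%         | -1.5 in old CD8 (NRF1/YY1 labels) |
| age_down_cd4         | ~1.5%         | -1.5 in old CD4 (ZBTB labels) |
| lineage              | 10%           | +1.5 in CD8 |

The lineage age budgets are `round(frac * n_peaks)` per lineage; a shared
`age_up` class of size `round(min(budgets)/2)` counts toward both, the rest
close lineage-specifically. Counts are negative binomial (gamma–Poisson,
dispersion 0.05 shared across groups) around group means scaled to a library
size drawn uniformly from 150k–300k in-peak insertions, plus a per-donor,
per-feature normal random intercept (SD 0.3) shared across that donor's six
samples — this is what the consensus-correlation GLS must absorb, and the
fitted rho (~0.4 at defaults) matches the implied intraclass correlation.
Motif labels are emitted per effect class with probability 0.6 (background
0.05 on all peaks, plus two decoy families). 163 synthetic ribosomal genes
(51 RPL, 34 RPS, 78 MRP) sit within 10 kb of distinct age_down_cd8 peaks
(cycling onto shared peaks only when the class is smaller than the set);
other genes sit near other peaks, and RNA counts inherit half the host
peak's effect, so accessibility and expression agree in direction but not
magnitude. Per-sample peak calls drop each atlas peak with probability 0.2
and jitter both ends by up to 10% of the width, which makes the >=2-sample /
50%-merge reconstruction non-trivial while guaranteeing (gaps >= 200 bp >
2 x max jitter) that calls from adjacent peaks never touch. Optional
insertion events place each counted event uniformly within its peak plus 10%
background insertions strictly between peaks, so recounting on the true
atlas reproduces the count matrix exactly.

What the generator does **not** emulate: sequence content and GC bias,
fragment-length structure, chromosomal heterogeneity, peak-width–signal
correlation, library-complexity saturation, and donor-specific biological
covariates beyond a random intercept. Passing tests therefore demonstrate
the statistical machinery — calibration, recovery, ranking behaviour —
under the design's noise model, not robustness to the full messiness of
real ATAC-seq.

## 8. Problem sizes and budgets in the test suite

The suite runs the full statistical checks at deliberately desk-scale sizes:
2000-peak cohorts for recovery, asymmetry and the ten end-to-end replicates;
500-peak fully-null cohorts (x20) for false-discovery calibration; 500 null
score cohorts with exhaustive enumeration (2^10 sign-flips, C(10,5)
relabellings) for permutation calibration; 100 random interval instances
(<= 200 intervals) against the naive all-pairs consensus oracle; and
60-point-per-cluster Gaussian mixtures for gap-statistic selection of
k in {1, 2, 3, 5}. These sizes were chosen so each property is measured
with comfortable statistical margin by an ordinary laptop-scale run.

## 9. Known limitations

* The sample-weight estimator ignores leverage, which slightly biases
  weights in very unbalanced designs; weights are clipped so the bias is
  bounded.
* One consensus rho for all features understates donor correlation for the
  most donor-variable features, exactly as in the consensus-correlation
  tradition; per-feature mixed models are out of scope.
* The trend statistic (Spearman + Stouffer) and the equal stratum weighting
  are reasonable defaults, not the only defensible ones; both are isolated
  behind the test's interface.
* EASE/Fisher enrichment assumes an unstructured background; no
  accessibility-matched background sampling is provided.
* The atlas midpoint-split rule for sub-threshold overlaps is a convention;
  alternatives (keeping overlaps, always unioning) change only peaks whose
  overlap is below half the shorter peak's length.
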