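# Methods

This note documents the statistical model behind each stage, the defaults
and their rationale, what the synthetic generator does and does not
emulate, and the numerical choices that matter for reproducibility.

## Per-study differential expression

Counts are normalized with TMM: the reference sample is the one whose
75th-percentile count fraction is closest to the mean of that quantity;
per-sample factors are 2 to the precision-weighted, doubly trimmed (30% on
M, 5% on A) mean of gene-wise M-values against the reference, computed on
library-size-normalized counts with zero-count genes excluded, and the
factors are rescaled to geometric mean one. Trim fractions are the
standard published defaults and are exposed as arguments. Expression is
then log2 CPM with a prior count of 0.5:
`log2((count + 0.5) / (lib·factor) · 1e6)`.

Microarray matrices are assumed already normalized on the log2 scale; a
scale heuristic (maximum value above 30) triggers a logged `log2(x+1)`
transform. No background correction, quantile normalization or batch
correction is attempted — study-level quality decisions are upstream of
this package.

The two-group model gives `y_g = mean(case) − mean(control)` with a
pooled-variance SE on `n − 2` df (paired designs use within-pair
differences on `n_pairs − 1` df). The moderated option shrinks gene
variances toward a common prior fitted by method of moments on
`log s²_g` under a scaled-F model (trigamma inversion by Newton's method,
tolerance 1e-10); prior df `d₀ = 0` recovers the ordinary t and
`d₀ = ∞` gives fully pooled variances. Zero residual variances are floored
at `sqrt(eps)` times the effect scale with a logged warning so that genes
are never silently dropped; the meta-analysis inherits these floors.

## Random-effects meta-analysis

Pooling is DerSimonian–Laird exactly as written in the README, with:

- evaluation rule: a gene enters the meta-analysis when measured in ≥ 2
  studies (`min_presence = 2`);
- significance: FDR < 0.05, |pooled log2FC| > 0.6, measured in ≥ 11
  studies — all strict inequalities, so a pooled effect of exactly 0.6 or
  coverage of exactly 10 studies does not flag;
- inference: normal z-test and 1.96-quantile CI (standard DL practice;
  no t-correction, no REML/Paule–Mandel alternatives);
- `τ² = 0` for k = 1 and `I² = max(0, (Q − (k−1))/Q)`.

The DL truncation `τ̂² = max(0, ·)` makes the z-test mildly conservative
under the exact null (inflated SE whenever `Q > k−1`). This is a property
of the estimator, not of the implementation: a sensitive uniformity test
on thousands of null genes sits close to its detection boundary, which is
why the calibration check is run at a fixed seed and the fraction of
FDR-significant null genes (zero in practice) is reported alongside it.

Leave-one-out sensitivity: a significant gene is `loo_stable` when all k
re-poolings keep the sign of the full estimate, keep |pooled| above the
effect-size threshold, and keep the unadjusted p below the FDR threshold.
Unadjusted p is used because re-running the global BH correction inside
each rerun would couple genes to one another. Forest/funnel exports are
pure data (per-study effects, CIs, random-effects weights, pseudo-CI cone
of half-width 1.96·SE); rendering is left to the caller or the HTML
report.

## Over-representation analysis

Hypergeometric upper tail `P(X ≥ k)` with universe defaulting to the
meta-analysis gene list intersected with gene-set membership — the
defensible default when the annotation source does not define one. BH runs
across all tested terms (any term with ≥ 1 member in the universe)
*before* the ≥ 10-overlap report filter; filtering first would bias the
FDR. The overlap rule is `k ≥ 10` (configurable). Over- and
under-expressed genes are tested separately against the same universe.

## Survival signatures

Quartiles use linear interpolation between order statistics (NumPy
default). Gene-wise screens compare the strict extremes (`z < Q1` vs
`z > Q3`; at n = 180 distinct values this yields 45 + 45 samples); ties at
the quartile are excluded by construction. The risk score counts genes
with `z > Q3` per sample and splits at the median count with
`count ≥ median ⇒ high risk` (a median of six means "at least six highly
expressed genes" is high risk; with median three, "three or more"). The
rule depends only on within-gene ranks, so risk labels are invariant to
monotone per-gene transformations.

KM estimation and the log-rank test are delegated to lifelines (with
validation and tabular output added). The Cox model is implemented here:
Newton–Raphson on the partial likelihood with Breslow ties by default
(Efron optional), observed-information standard errors, step halving,
convergence at relative log-likelihood change < 1e-9 within 50
iterations; non-convergence and extreme coefficients (|β| > 15, a
monotone-likelihood signature) are flagged but estimates are returned.
The score test at β = 0 is exposed separately because, for a single binary
covariate without ties, it coincides with the log-rank statistic — a
useful cross-check between the two code paths. Co-occurrence grouping is
average-linkage clustering on Jaccard distances of the gene indicator
vectors with a configurable k-cluster cut (default 2).

Time units are caller-defined throughout; the package never assumes
months versus days.

## Synthetic data

The generator reproduces the statistical structure, not the biology, of a
multi-study compendium:

- 21 studies by default (19 array-like, 2 count-based), per-study sizes
  spread evenly to total 320 controls and 602 cases, every group ≥ 5;
- per-gene truth: a fraction `de_fraction = 0.1` of genes carry mean
  effect `μ_g = ±effect_size_mean` (±1 log2 by default, random sign) with
  between-study SD `τ = 0.2`; per-study realized effects are
  `δ_gj ~ N(μ_g, τ²)` — exactly the random-effects model DL assumes.
  Null genes have `τ_g = 0`;
- arrays: Gaussian log2 intensities, gene baselines `N(7, 1.5²)`, residual
  SD 0.8 (a typical microarray residual scale); RNA-seq:
  gamma-Poisson (negative binomial) counts with dispersion 0.1 and
  log-normal library sizes around 10⁶, case mean ratio `2^δ_gj`;
- coverage: each study measures each gene independently with probability
  0.5, plus a 10% always-measured core, so roughly half the genes pass
  the ≥ 11-study filter — mimicking heterogeneous platform coverage;
- seeding: one root seed spawns a truth stream and one stream per study,
  so adding studies never reshuffles earlier ones and identical
  configurations are byte-reproducible.

The calibration and recovery checks use `coverage_fraction = 1` so that
they measure the pooling statistic itself rather than coverage-induced
attrition of the ≥ 11-study filter; coverage effects are tested
separately through the bookkeeping tests.

The survival generator draws a latent risk class (half the cohort by
default), exponential event times with hazard `baseline_rate` (1/30 per
time unit) multiplied by `hazard_ratio` for the high-risk class, and
independent exponential censoring (rate 0.01) — the non-informative
censoring KM assumes. Signature genes are shifted by 1.5 SD in high-risk
samples before z-scoring, giving expected per-sample counts of highly
expressed genes near 15/28 (high risk) versus 2/28 (low risk), so the
median-count split recovers the latent class with few misclassifications.
The estimated hazard ratio of the *derived* risk groups is mildly
attenuated relative to the generative one (misclassification plus the
median split), which the stratification checks accommodate.

What the generator does not emulate: probe-level structure and
probe-to-gene mapping, platform-specific intensity distributions, batch
effects, correlated genes, informative censoring and clinical covariates
correlated with expression. Passing tests therefore demonstrate
correctness of the statistical machinery under its stated model, not
robustness to those real-data complications.

## Problem sizes

The calibration and recovery runs use 21 studies × 2,000 genes (a few
seconds each); determinism and smoke tests use 3 studies × 150–200 genes;
survival checks use cohorts of 200 samples and a large-sample Cox
cross-check at n = 2,000. These sizes give Monte-Carlo error comfortably
inside every tolerance asserted.
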