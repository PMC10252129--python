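# txmeta

Random-effects meta-analysis of multi-study transcriptomic case/control
compendia, with downstream over-representation analysis and quartile-based
survival gene signatures. The package targets the common situation in
cancer transcriptomics — many small public case/control studies on mixed
platforms (normalized microarray intensities and RNA-seq counts), no shared
normalization, incomplete gene coverage — where pooling per-study effect
sizes is more robust than merging raw expression matrices. A synthetic-data
module generates compendia and survival cohorts with known ground truth for
validating every stage.

## Method

**Per-study differential expression.** RNA-seq counts are normalized with
TMM (trimmed mean of M-values) scale factors and converted to log2 CPM;
microarray matrices are taken as normalized log2 intensities. Each study is
reduced to per-gene effects by a two-group linear model (paired or
unpaired): effect y = log2FC (case − control) with standard error from the
pooled residual variance, optionally moderated by empirical-Bayes variance
shrinkage (`s̃²_g = (d₀s₀² + d·s²_g)/(d₀ + d)` with `d₀, s₀²` estimated by
method of moments on the log variances). P-values are BH-adjusted.

**Random-effects pooling.** For each gene measured in ≥ 2 studies the
per-study effects `y_j` with variances `v_j` are pooled under
`y_j ~ N(θ + u_j, v_j)`, `u_j ~ N(0, τ²)`, with the DerSimonian–Laird
moment estimator:

```
w_j = 1/v_j          Q = Σ w_j (y_j − ȳ_FE)²       C = Σw − Σw²/Σw
τ̂² = max(0, (Q − (k−1))/C)        θ̂ = Σ y_j/(v_j+τ̂²) / Σ 1/(v_j+τ̂²)
```

with a normal z-test, 95% CI `θ̂ ± 1.96·SE`, and BH adjustment across genes.
Genes are significant when FDR < 0.05, |log2FC| > 0.6 and measured in at
least 11 studies; each significant gene gets a leave-one-out stability flag
(sign, effect size and nominal significance retained in all k re-poolings)
plus forest/funnel plot data.

**Enrichment.** Significant genes (up- and down-regulated separately) are
tested against GMT gene sets by the hypergeometric upper tail, BH-adjusted
over all tested terms; reported terms need ≥ 10 overlapping genes and
FDR < 0.05.

**Survival signatures.** On a cohort with per-gene expression z-scores,
each signature gene is binarized at its upper quartile (1 iff z > Q3); the
per-sample count of highly expressed genes is split at the median count
(count ≥ median ⇒ high risk). Risk groups are compared by Kaplan–Meier
curves and the log-rank test, the risk label can enter a multivariate Cox
proportional-hazards model (Newton–Raphson partial likelihood, Breslow or
Efron ties), and gene co-occurrence is grouped by average-linkage
clustering on Jaccard distances of the indicator vectors.

## Worked example

```python
from txmeta import (MetaConfig, SimulationConfig, dl_pool, run_meta,
                    signature_score, simulate_multistudy, simulate_survival_cohort)
from txmeta.preprocess import fit_dge, normalize_study

# pooling three studies measuring the same gene
res = dl_pool([1.0, 0.5, 1.5], [0.04, 0.04, 0.04])
print(f"pooled log2FC = {res.pooled:.3f} (SE {res.se:.4f})")
print(f"tau^2 = {res.tau2:.3f}, Q = {res.q:.2f}, 95% CI [{res.ci_low:.3f}, {res.ci_high:.3f}]")

# a 21-study synthetic compendium with 10% truly DE genes
cfg = SimulationConfig(n_studies=21, n_genes=2000, de_fraction=0.1, seed=0)
studies, truth = simulate_multistudy(cfg)
dges = [fit_dge(normalize_study(s)) for s in studies]
meta = run_meta(dges, MetaConfig())
print(meta.table[["k", "log2fc", "se", "fdr", "tau2", "significant"]].head(3).round(4))

# survival signature on a 200-sample cohort with a built-in hazard ratio
cohort, struth = simulate_survival_cohort(n_samples=200, hazard_ratio=2.36, seed=0)
sig = signature_score(cohort, struth.survival["signature_genes"], cox=True)
print(f"cutoff = {sig.cutoff:.0f}; log-rank p = {sig.logrank[2]:.2e}; "
      f"Cox HR = {sig.cox.summary.loc['high_risk','hr']:.2f}")
```

Output:

```
pooled log2FC = 1.000 (SE 0.2887)
tau^2 = 0.210, Q = 12.50, 95% CI [0.434, 1.566]
        k  log2fc      se  fdr    tau2  significant
G0410  21  1.0041  0.0526  0.0  0.0030         True
G1369  21 -0.9106  0.0526  0.0  0.0033         True
G1684  15  1.1180  0.0664  0.0  0.0125         True
cutoff = 6; log-rank p = 3.98e-05; Cox HR = 1.93
```

The pooled estimate of 1.000 is the heterogeneity-weighted mean of the
three study effects; τ² = 0.21 quantifies their between-study variance.
In the compendium run the top genes recover their simulated ±1 log2FC
effects; in the survival run the median count of highly expressed
signature genes (6) splits the cohort into risk groups whose survival
curves differ strongly (log-rank p ≈ 4·10⁻⁵) with a high-risk hazard
ratio near the simulated value.

There is also a CLI: `txmeta simulate | dge | meta | ora | survival | run`
(see `txmeta run --config pipeline.yaml` for the end-to-end pipeline with
a JSON run manifest and a static HTML report).

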