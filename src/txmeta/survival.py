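"""Survival analysis: quartile groups, KM/log-rank, risk-score signatures, Cox.

The signature procedure binarizes each signature gene at its cohort upper
quartile (1 = z-score strictly above Q3), counts highly expressed genes per
sample, and splits the cohort at the median count: samples with at least the
median count form the high-risk group. Groups are compared by Kaplan–Meier
curves and the log-rank test, and the risk label can enter a multivariate
Cox proportional-hazards model alongside clinical covariates.

KM estimation and the log-rank test are delegated to lifelines; the Cox
model is fit here by Newton–Raphson on the partial likelihood (Breslow tie
handling by default, Efron optional) so that the score test at beta = 0 —
which coincides with the log-rank statistic for a single binary covariate
without ties — is available in closed form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .containers import ValidationError

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054


# ---------------------------------------------------------------------------
# Cohort container
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCohort:
    """Sample-level follow-up plus a gene x sample z-score matrix.

    ``table`` is indexed by sample ID with columns ``time`` (> 0, units are
    caller-defined) and ``event`` (1 = event observed, 0 = censored);
    ``expression`` columns must match the table index.
    """

    table: pd.DataFrame
    expression: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("time", "event"):
            if col not in self.table.columns:
                raise ValidationError(f"survival table lacks {col!r}")
        if not self.table.index.is_unique:
            raise ValidationError("duplicate sample IDs")
        if (self.table["time"] <= 0).any():
            raise ValidationError("survival times must be positive")
        if not set(self.table["event"].unique()) <= {0, 1}:
            raise ValidationError("event indicator must be 0/1")
        if not self.expression.columns.equals(self.table.index):
            if set(self.expression.columns) != set(self.table.index):
                raise ValidationError("expression samples != survival samples")
            self.expression = self.expression[self.table.index]

    @property
    def times(self) -> np.ndarray:
        return self.table["time"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.table["event"].to_numpy(dtype=int)


# ---------------------------------------------------------------------------
# Expression preparation
# ---------------------------------------------------------------------------

def zscore_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores ((x - mean) / SD, SD with n-1); zero-SD genes dropped."""
    if expr.shape[1] < 2:
        raise ValidationError("z-scoring requires >= 2 samples")
    sd = expr.std(axis=1, ddof=1)
    dropped = int((sd == 0).sum())
    if dropped:
        logger.warning("z-score: dropping %d constant genes", dropped)
    keep = sd > 0
    if not keep.any():
        raise ValidationError("all genes have zero variance")
    centered = expr.loc[keep].sub(expr.loc[keep].mean(axis=1), axis=0)
    return centered.div(sd[keep], axis=0)


def quartile_groups(z: pd.Series | np.ndarray) -> tuple[pd.Index, pd.Index]:
    """Split samples into low (< Q1) and high (> Q3) expression groups.

    Quartiles use linear interpolation between order statistics; the
    inequalities are strict, so samples at or between the quartiles are
    excluded from the gene-wise comparison.
    """
    s = pd.Series(z) if not isinstance(z, pd.Series) else z
    if s.size < 8:
        raise ValidationError("quartile grouping requires >= 8 samples")
    q1, q3 = np.quantile(s.to_numpy(dtype=float), [0.25, 0.75])
    low = s.index[s.to_numpy() < q1]
    high = s.index[s.to_numpy() > q3]
    if len(low) == 0 or len(high) == 0:
        raise ValidationError(
            f"degenerate expression distribution (Q1={q1:g}, Q3={q3:g}): "
            f"{getattr(s, 'name', None) or 'gene'} has an empty extreme group"
        )
    return low, high


# ---------------------------------------------------------------------------
# Kaplan–Meier and log-rank
# ---------------------------------------------------------------------------

def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival curve.

    Returns one row per distinct time (plus t = 0) with columns ``time``,
    ``survival``, ``at_risk``, ``events`` and ``censored``; ``survival`` is
    the right-continuous KM estimate S(t) = prod_{t_i <= t} (1 - d_i/n_i).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValidationError("empty sample")
    if (t < 0).any():
        raise ValidationError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "survival": surv.reindex(table.index).to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(dtype=int),
            "events": table["observed"].to_numpy(dtype=int),
            "censored": table["censored"].to_numpy(dtype=int),
        }
    )
    if out.iloc[0]["time"] != 0.0:
        first = pd.DataFrame(
            [{"time": 0.0, "survival": 1.0, "at_risk": t.size, "events": 0, "censored": 0}]
        )
        out = pd.concat([first, out], ignore_index=True)
    return out


def logrank_test(group_a, group_b) -> tuple[float, int, float]:
    """Mantel–Haenszel log-rank test between two (times, events) groups.

    Returns (chi-square statistic, df = 1, p-value).
    """
    ta, ea = np.asarray(group_a[0], dtype=float), np.asarray(group_a[1], dtype=int)
    tb, eb = np.asarray(group_b[0], dtype=float), np.asarray(group_b[1], dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise ValidationError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValidationError("log-rank undefined with zero events")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), 1, float(res.p_value)


# ---------------------------------------------------------------------------
# Cox proportional hazards (Newton–Raphson partial likelihood)
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Cox model fit: per-covariate estimates plus fit diagnostics."""

    summary: pd.DataFrame  # coef, hr, se, z, p, ci_low, ci_high per covariate
    log_likelihood: float
    converged: bool
    n: int
    n_events: int
    ties: str


def _cox_loglik(beta, x, times, events, ties):
    """Log partial likelihood, gradient and information (negative Hessian).

    Rows must be sorted by ascending time; the risk set at an event time is
    every sample with time >= t (suffix sums). Breslow uses the full risk
    set for every tied event; Efron down-weights the tied events' own
    contributions by l/d, l = 0..d-1.
    """
    n, p = x.shape
    eta = x @ beta
    r = np.exp(eta)
    rx = r[:, None] * x
    rxx = np.einsum("i,ij,ik->ijk", r, x, x)

    # suffix cumulative sums over the time-sorted rows
    s0 = np.cumsum(r[::-1])[::-1]
    s1 = np.cumsum(rx[::-1], axis=0)[::-1]
    s2 = np.cumsum(rxx[::-1], axis=0)[::-1]

    loglik = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and times[j] == times[i]:
            j += 1
        ev = [idx for idx in range(i, j) if events[idx] == 1]
        d = len(ev)
        if d:
            xs = x[ev].sum(axis=0)
            loglik += eta[ev].sum()
            if ties == "breslow":
                loglik -= d * np.log(s0[i])
                mean = s1[i] / s0[i]
                grad += xs - d * mean
                info += d * (s2[i] / s0[i] - np.outer(mean, mean))
            else:  # efron
                rd = r[ev].sum()
                rd1 = rx[ev].sum(axis=0)
                rd2 = rxx[ev].sum(axis=0)
                for ell in range(d):
                    f = ell / d
                    denom = s0[i] - f * rd
                    mean = (s1[i] - f * rd1) / denom
                    loglik -= np.log(denom)
                    grad -= mean
                    info += (s2[i] - f * rd2) / denom - np.outer(mean, mean)
                grad += xs
        i = j
    return loglik, grad, info


def cox_fit(
    cohort_or_table,
    covariates: pd.DataFrame | None = None,
    ties: str = "breslow",
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton–Raphson.

    ``cohort_or_table`` is a :class:`SurvivalCohort` or a DataFrame with
    ``time``/``event`` columns; ``covariates`` is a sample x covariate
    numeric table aligned on the same index (category encoding is the
    caller's responsibility). Standard errors come from the observed
    information at the optimum; convergence requires a relative change in
    log partial likelihood below ``tol`` (non-convergence and monotone
    likelihoods are flagged, with estimates still returned).
    """
    if ties not in ("breslow", "efron"):
        raise ValidationError(f"unknown tie method {ties!r}")
    if isinstance(cohort_or_table, SurvivalCohort):
        table = cohort_or_table.table
    else:
        table = cohort_or_table
    if covariates is None:
        cov_cols = [c for c in table.columns if c not in ("time", "event")]
        covariates = table[cov_cols]
    covariates = covariates.loc[table.index]
    if covariates.shape[1] == 0:
        raise ValidationError("at least one covariate required")
    n_events = int(table["event"].sum())
    if n_events < covariates.shape[1]:
        raise ValidationError("fewer events than covariates")

    order = np.argsort(table["time"].to_numpy(), kind="mergesort")
    times = table["time"].to_numpy(dtype=float)[order]
    events = table["event"].to_numpy(dtype=int)[order]
    x = covariates.to_numpy(dtype=float)[order]
    p = x.shape[1]

    beta = np.zeros(p)
    loglik, grad, info = _cox_loglik(beta, x, times, events, ties)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            logger.warning("Cox: singular information matrix")
            break
        new_beta = beta + step
        new_ll, new_grad, new_info = _cox_loglik(new_beta, x, times, events, ties)
        halvings = 0
        while new_ll < loglik and halvings < 20:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_info = _cox_loglik(new_beta, x, times, events, ties)
            halvings += 1
        rel = abs(new_ll - loglik) / max(1.0, abs(loglik))
        beta, loglik, grad, info = new_beta, new_ll, new_grad, new_info
        if rel < tol:
            converged = True
            break
    if not converged:
        logger.warning("Cox: Newton–Raphson did not converge (possible separation)")
    if np.abs(beta).max() > 15:
        logger.warning("Cox: extreme coefficients; likely monotone likelihood")
        converged = False

    try:
        cov_beta = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov_beta))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    summary = pd.DataFrame(
        {
            "coef": beta,
            "hr": np.exp(beta),
            "se": se,
            "z": z,
            "p": pvals,
            "ci_low": np.exp(beta - Z95 * se),
            "ci_high": np.exp(beta + Z95 * se),
        },
        index=covariates.columns,
    )
    return CoxFit(
        summary=summary,
        log_likelihood=float(loglik),
        converged=converged,
        n=len(table),
        n_events=n_events,
        ties=ties,
    )


def cox_score_test(times, events, x) -> tuple[float, float]:
    """Partial-likelihood score test at beta = 0 for a single covariate.

    For a binary covariate without tied event times this statistic equals
    the log-rank chi-square. Returns (statistic, p).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    xv = np.asarray(x, dtype=float).reshape(-1, 1)
    order = np.argsort(t, kind="mergesort")
    _, grad, info = _cox_loglik(np.zeros(1), xv[order], t[order], e[order], "breslow")
    stat = float(grad[0] ** 2 / info[0, 0])
    return stat, float(stats.chi2.sf(stat, 1))


# ---------------------------------------------------------------------------
# Risk-score signature
# ---------------------------------------------------------------------------

@dataclass
class SignatureResult:
    """Count-based risk signature: indicators, counts, groups and tests."""

    genes: list[str]
    indicator: pd.DataFrame  # gene x sample 0/1, 1 = z above the gene's Q3
    counts: pd.Series  # per-sample number of highly expressed genes
    cutoff: float  # median count; high risk iff count >= cutoff
    risk: pd.Series  # "high" / "low" per sample
    km: dict[str, pd.DataFrame] = field(default_factory=dict)
    logrank: tuple[float, int, float] | None = None
    cox: CoxFit | None = None


def signature_score(
    cohort: SurvivalCohort,
    genes,
    cox: bool = False,
) -> SignatureResult:
    """Count-of-highly-expressed-genes risk score with a median cutoff.

    Each signature gene is binarized at its upper quartile across the cohort
    (1 iff z > Q3); per-sample counts are split at the median count, with
    counts at or above the median labeled high risk (a median of six means
    "at least six highly expressed genes" is high risk). KM curves per risk
    group and the log-rank comparison are attached; with ``cox=True`` a
    univariate Cox fit of the high-risk indicator is included.
    """
    genes = list(genes)
    present = [g for g in genes if g in cohort.expression.index]
    missing = sorted(set(genes) - set(present))
    if missing:
        logger.warning("signature: %d genes absent from matrix: %s", len(missing), missing[:5])
    if not present:
        raise ValidationError("no signature gene present in the expression matrix")

    z = cohort.expression.loc[present]
    q3 = z.quantile(0.75, axis=1)
    indicator = (z.gt(q3, axis=0)).astype(int)
    counts = indicator.sum(axis=0)
    cutoff = float(np.median(counts.to_numpy()))
    risk = pd.Series(np.where(counts >= cutoff, "high", "low"), index=counts.index)

    km = {}
    groups = {}
    for label in ("high", "low"):
        idx = risk.index[risk == label]
        sub = cohort.table.loc[idx]
        groups[label] = (sub["time"].to_numpy(), sub["event"].to_numpy())
        if len(idx):
            km[label] = km_estimate(*groups[label])
    lr = None
    if len(groups["high"][0]) and len(groups["low"][0]):
        lr = logrank_test(groups["high"], groups["low"])

    cox_fit_result = None
    if cox:
        covars = pd.DataFrame({"high_risk": (risk == "high").astype(float)})
        covars.index = risk.index
        cox_fit_result = cox_fit(cohort.table, covars)

    return SignatureResult(
        genes=present,
        indicator=indicator,
        counts=counts,
        cutoff=cutoff,
        risk=risk,
        km=km,
        logrank=lr,
        cox=cox_fit_result,
    )


def gene_km_screen(cohort: SurvivalCohort, genes=None) -> pd.DataFrame:
    """Gene-wise KM screen on the quartile extreme groups.

    For each gene, samples below Q1 and above Q3 of its z-score are compared
    by log-rank; returns a table with the group sizes, chi-square statistic,
    p and BH-adjusted p across the screened genes.
    """
    from .preprocess import bh_adjust

    genes = list(genes) if genes is not None else list(cohort.expression.index)
    rows = []
    for g in genes:
        if g not in cohort.expression.index:
            continue
        z = cohort.expression.loc[g]
        try:
            low, high = quartile_groups(z)
        except ValidationError:
            continue
        sub_low = cohort.table.loc[low]
        sub_high = cohort.table.loc[high]
        try:
            stat, _, p = logrank_test(
                (sub_high["time"].to_numpy(), sub_high["event"].to_numpy()),
                (sub_low["time"].to_numpy(), sub_low["event"].to_numpy()),
            )
        except ValidationError:
            continue
        rows.append({"gene": g, "n_low": len(low), "n_high": len(high), "chi2": stat, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Co-occurrence of highly expressed genes
# ---------------------------------------------------------------------------

def jaccard_matrix(indicator: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard similarity of gene indicator vectors."""
    m = indicator.to_numpy(dtype=bool)
    inter = (m[:, None, :] & m[None, :, :]).sum(axis=2).astype(float)
    union = (m[:, None, :] | m[None, :, :]).sum(axis=2).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        j = np.where(union > 0, inter / union, 1.0)
    return pd.DataFrame(j, index=indicator.index, columns=indicator.index)


def cooccurrence_groups(indicator: pd.DataFrame, k: int = 2) -> dict:
    """Group genes by co-occurrence of their high-expression indicators.

    Genes are clustered by average-linkage hierarchical clustering on
    Jaccard distance (1 - similarity) of their 0/1 vectors; returns the
    dendrogram leaf ordering, a k-cluster cut, and the gene x gene
    co-occurrence count matrix.
    """
    m = indicator.to_numpy(dtype=int)
    if m.size == 0 or m.sum() == 0:
        raise ValidationError("co-occurrence needs a non-empty, non-zero indicator matrix")
    jac = jaccard_matrix(indicator)
    dist = 1.0 - jac.to_numpy()
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    order = hierarchy.leaves_list(link)
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    cooc = pd.DataFrame(m @ m.T, index=indicator.index, columns=indicator.index)
    return {
        "order": [indicator.index[i] for i in order],
        "clusters": pd.Series(labels, index=indicator.index, name="cluster"),
        "jaccard": jac,
        "cooccurrence": cooc,
        "linkage": link,
    }
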