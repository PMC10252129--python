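"""Per-study normalization and differential expression.

RNA-seq count matrices are scaled with TMM (trimmed mean of M-values) factors
and converted to log2 CPM; microarray matrices are assumed pre-normalized on
the log2 scale (a scale heuristic log2-transforms them if needed). Each study
is then reduced to a per-gene table of log2 fold changes and standard errors
by a two-group linear model — ordinary or moderated t, paired or unpaired —
which is what the downstream random-effects meta-analysis consumes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .containers import (
    CASE,
    CONTROL,
    NORMALIZED_LOG2,
    RAW_COUNTS,
    RNASEQ,
    DGEResult,
    ExpressionStudy,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: log2 values above this suggest an un-logged matrix
LOG2_SCALE_MAX = 30.0


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def tmm_factors(
    counts: pd.DataFrame | np.ndarray,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors, one per sample.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean of that quantity across samples. For every sample,
    M (log-ratio) and A (log-abundance) values versus the reference are
    computed on library-size-normalized counts, genes with a zero in either
    sample are dropped, the M values are trimmed by ``trim_m`` on each side
    and the A values by ``trim_a``, and the factor is two raised to the
    precision-weighted mean of the surviving M values (weights = inverse
    asymptotic binomial variance). Factors are rescaled to geometric mean 1.
    """

    x = np.asarray(counts, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValidationError("TMM requires a gene x sample matrix with >= 2 samples")
    if (x < 0).any():
        raise ValidationError("negative counts")
    lib = x.sum(axis=0)
    if (lib == 0).any():
        raise ValidationError("sample with zero library size")

    frac = x / lib
    f75 = np.quantile(frac, 0.75, axis=0)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    log_factors = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        if j == ref:
            continue
        log_factors[j] = _tmm_pair(x[:, j], x[:, ref], lib[j], lib[ref], trim_m, trim_a)

    log_factors -= log_factors.mean()  # geometric mean 1
    return 2.0 ** log_factors


def _tmm_pair(obs, ref, lib_obs, lib_ref, trim_m, trim_a) -> float:
    """log2 TMM factor of one sample against the reference."""
    keep = (obs > 0) & (ref > 0)
    obs_k, ref_k = obs[keep], ref[keep]
    if obs_k.size == 0:
        logger.warning("TMM: no genes shared with reference; factor set to 1")
        return 0.0

    p_obs = obs_k / lib_obs
    p_ref = ref_k / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic binomial variance of M
    v = (lib_obs - obs_k) / (lib_obs * obs_k) + (lib_ref - ref_k) / (lib_ref * ref_k)

    n = m.size
    lo_m, hi_m = int(np.floor(n * trim_m)), n - int(np.floor(n * trim_m))
    lo_a, hi_a = int(np.floor(n * trim_a)), n - int(np.floor(n * trim_a))
    rank_m = stats.rankdata(m, method="ordinal")
    rank_a = stats.rankdata(a, method="ordinal")
    keep2 = (rank_m > lo_m) & (rank_m <= hi_m) & (rank_a > lo_a) & (rank_a <= hi_a)
    if keep2.sum() < 2:
        logger.warning("TMM: fewer than 2 genes survive trimming; factor set to 1")
        return 0.0
    w = 1.0 / v[keep2]
    return float(np.sum(w * m[keep2]) / np.sum(w))


def log_cpm(
    counts: pd.DataFrame | np.ndarray,
    factors: np.ndarray | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame | np.ndarray:
    """log2 counts per million on TMM-effective library sizes.

    value = log2((count + prior_count) / (library_size * factor) * 1e6)
    """
    x = np.asarray(counts, dtype=float)
    lib = x.sum(axis=0)
    if factors is None:
        factors = np.ones(x.shape[1])
    factors = np.asarray(factors, dtype=float)
    if (factors <= 0).any():
        raise ValidationError("TMM factors must be positive")
    out = np.log2((x + prior_count) / (lib * factors) * 1e6)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out


def normalize_study(study: ExpressionStudy, prior_count: float = 0.5) -> ExpressionStudy:
    """Bring a study to the normalized log2 scale expected by ``fit_dge``.

    Raw RNA-seq counts get TMM + log-CPM; array matrices that look un-logged
    (max value above 30) are log2(x+1)-transformed with a logged notice.
    """
    if study.normalization_state == RAW_COUNTS:
        factors = tmm_factors(study.matrix)
        logm = log_cpm(study.matrix, factors, prior_count=prior_count)
        return ExpressionStudy(
            study_id=study.study_id,
            matrix=logm,
            samples=study.samples,
            platform=study.platform,
            normalization_state=NORMALIZED_LOG2,
        )
    if study.matrix.to_numpy().max() > LOG2_SCALE_MAX:
        logger.info("%s: values look un-logged; applying log2(x+1)", study.study_id)
        return ExpressionStudy(
            study_id=study.study_id,
            matrix=np.log2(study.matrix + 1.0),
            samples=study.samples,
            platform=study.platform,
            normalization_state=NORMALIZED_LOG2,
        )
    return study


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-down adjusted p-values (monotone, in [0, 1])."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on a log-convex scale)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return float(y)


def _fit_scaled_f(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment estimation of the variance prior (d0, s0^2) on log s^2.

    Fits the scaled-F model underlying the moderated t: the log sample
    variances minus their known chi-square expectation have variance
    trigamma(df/2) + trigamma(d0/2); inverting the excess variance gives d0.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(e.mean()))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_2 = float(np.exp(e.mean() + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def fit_dge(
    study: ExpressionStudy,
    paired: bool = False,
    moderated: bool = True,
    prior_df: float | None = None,
) -> DGEResult:
    """Two-group differential expression for one normalized study.

    Unpaired: per-gene effect = mean(case) - mean(control) with a
    pooled-variance standard error on n - 2 degrees of freedom. Paired:
    the model is fit on within-pair case-minus-control differences with
    n_pairs - 1 degrees of freedom. With ``moderated=True`` the gene-wise
    variances are shrunk toward a common prior estimated by the method of
    moments on log variances (empirical-Bayes moderated t); ``prior_df``
    overrides the estimated prior degrees of freedom (0 recovers the
    ordinary t, ``numpy.inf`` fully shrinks every variance to the prior).

    Returns a :class:`DGEResult` with BH-adjusted p-values.
    """
    if study.normalization_state != NORMALIZED_LOG2:
        raise ValidationError(
            f"{study.study_id}: fit_dge requires a normalized log2 matrix "
            "(run normalize_study first)"
        )
    x = study.matrix
    if paired:
        effect, s2, df = _paired_stats(study)
    else:
        ctrl = x[study.control_samples].to_numpy()
        case = x[study.case_samples].to_numpy()
        n_c, n_t = ctrl.shape[1], case.shape[1]
        effect = case.mean(axis=1) - ctrl.mean(axis=1)
        ss = ctrl.var(axis=1, ddof=1) * (n_c - 1) + case.var(axis=1, ddof=1) * (n_t - 1)
        df = float(n_c + n_t - 2)
        s2 = ss / df * (1.0 / n_c + 1.0 / n_t)  # variance of the effect

    if moderated:
        # the design constant multiplying s_g^2 is shared by all genes, so
        # shrinkage can act directly on the effect-scale variances
        raw = s2
        if prior_df is None:
            d0, s0_2 = _fit_scaled_f(raw, df)
        else:
            d0 = float(prior_df)
            _, s0_2 = _fit_scaled_f(raw, df)
        if np.isinf(d0):
            s2_mod = np.full_like(raw, s0_2)
            df_total = np.inf
        elif d0 == 0:
            s2_mod, df_total = raw, df
        else:
            s2_mod = (d0 * s0_2 + df * raw) / (d0 + df)
            df_total = df + d0
        s2_use, df_use = s2_mod, df_total
    else:
        s2_use, df_use = s2, df

    se = np.sqrt(s2_use)
    zero = se <= 0
    if zero.any():
        floor = np.sqrt(np.finfo(float).eps) * max(1.0, float(np.abs(effect).max()))
        logger.warning(
            "%s: %d genes with zero residual variance; SE floored", study.study_id, zero.sum()
        )
        se = np.where(zero, floor, se)

    t = effect / se
    if np.isinf(df_use):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_use)
    table = pd.DataFrame(
        {
            "log2fc": effect,
            "se": se,
            "df": df_use,
            "t": t,
            "p": p,
            "fdr": bh_adjust(p),
        },
        index=x.index,
    )
    return DGEResult(study_id=study.study_id, table=table, paired=paired, moderated=moderated)


def _paired_stats(study: ExpressionStudy) -> tuple[np.ndarray, np.ndarray, float]:
    sheet = study.samples.loc[study.matrix.columns]
    if "pair_id" not in sheet.columns or sheet["pair_id"].isna().any():
        raise ValidationError(f"{study.study_id}: paired design requires pair_id for all samples")
    diffs = []
    for pair, sub in sheet.groupby("pair_id"):
        ctrl = sub.index[(sub["group"] == CONTROL).to_numpy()]
        case = sub.index[(sub["group"] == CASE).to_numpy()]
        if len(ctrl) != 1 or len(case) != 1:
            raise ValidationError(
                f"{study.study_id}: pair {pair!r} must have exactly one case and one control"
            )
        diffs.append(study.matrix[case[0]].to_numpy() - study.matrix[ctrl[0]].to_numpy())
    d = np.column_stack(diffs)
    n_pairs = d.shape[1]
    if n_pairs < 2:
        raise ValidationError(f"{study.study_id}: need >= 2 pairs")
    effect = d.mean(axis=1)
    s2 = d.var(axis=1, ddof=1) / n_pairs
    return effect, s2, float(n_pairs - 1)
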