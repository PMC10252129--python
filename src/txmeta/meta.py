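"""Per-gene DerSimonian–Laird random-effects meta-analysis.

Each gene's per-study log2 fold changes y_j with variances v_j are pooled
under the random-effects model y_j ~ N(theta + u_j, v_j), u_j ~ N(0, tau^2),
with the DerSimonian–Laird moment estimator of the between-study variance:

    w_j   = 1 / v_j                    (fixed-effect weights)
    Q     = sum w_j (y_j - ybar_FE)^2  (Cochran heterogeneity statistic)
    C     = sum w - sum w^2 / sum w
    tau^2 = max(0, (Q - (k - 1)) / C)

Pooling then uses weights 1 / (v_j + tau^2); inference on the pooled effect
is a normal z-test with a 1.96-quantile 95% confidence interval, and BH
adjustment runs across all evaluated genes. Genes are declared significant
when FDR < 0.05, |pooled log2FC| > 0.6 and the gene was measured in at
least 11 studies (all thresholds configurable), and each significant gene
carries a leave-one-out stability flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DGEResult, ValidationError
from .preprocess import bh_adjust

Z95 = 1.959963984540054  # normal 97.5% quantile


@dataclass
class MetaConfig:
    """Evaluation and significance thresholds for the pooled results."""

    fdr_max: float = 0.05
    lfc_min: float = 0.6
    min_studies: int = 11
    min_presence: int = 2

    def __post_init__(self) -> None:
        if self.fdr_max <= 0 or self.lfc_min <= 0:
            raise ValidationError("thresholds must be positive")
        if self.min_studies < self.min_presence:
            raise ValidationError("min_studies must be >= min_presence")


@dataclass
class DLPooled:
    """Result of pooling one gene's per-study effects."""

    pooled: float
    se: float
    tau2: float
    q: float
    i2: float
    z: float
    p: float
    ci_low: float
    ci_high: float
    k: int


def dl_pool(effects, variances) -> DLPooled:
    """DerSimonian–Laird random-effects pooling of k study effects.

    ``effects`` are per-study log2 fold changes, ``variances`` their squared
    standard errors (all positive). With k = 1 the single study is passed
    through with tau^2 = 0.
    """
    y = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    if y.shape != v.shape or y.ndim != 1:
        raise ValidationError("effects and variances must be equal-length 1-D")
    k = y.size
    if k == 0:
        raise ValidationError("cannot pool zero studies")
    if (v <= 0).any() or not np.isfinite(v).all():
        raise ValidationError("variances must be positive and finite")

    w = 1.0 / v
    sw = w.sum()
    ybar = float((w * y).sum() / sw)
    q = float((w * (y - ybar) ** 2).sum())
    if k == 1:
        tau2 = 0.0
    else:
        c = sw - (w ** 2).sum() / sw
        tau2 = max(0.0, (q - (k - 1)) / c)
    ws = 1.0 / (v + tau2)
    pooled = float((ws * y).sum() / ws.sum())
    se = float(ws.sum() ** -0.5)
    z = pooled / se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    i2 = max(0.0, (q - (k - 1)) / q) if q > 0 else 0.0
    return DLPooled(
        pooled=pooled,
        se=se,
        tau2=tau2,
        q=q,
        i2=i2,
        z=z,
        p=p,
        ci_low=pooled - Z95 * se,
        ci_high=pooled + Z95 * se,
        k=k,
    )


def _dl_pool_matrix(y: np.ndarray, v: np.ndarray):
    """Vectorized DL pooling over genes (rows); NaN marks a missing study."""
    mask = np.isfinite(y) & np.isfinite(v)
    w = np.where(mask, 1.0 / np.where(mask, v, 1.0), 0.0)
    k = mask.sum(axis=1)
    sw = w.sum(axis=1)
    ybar = np.einsum("ij,ij->i", w, np.where(mask, y, 0.0)) / sw
    q = np.einsum("ij,ij->i", w, np.where(mask, (y - ybar[:, None]) ** 2, 0.0))
    c = sw - (w ** 2).sum(axis=1) / sw
    with np.errstate(invalid="ignore", divide="ignore"):
        tau2 = np.where(k > 1, np.maximum(0.0, (q - (k - 1)) / c), 0.0)
    ws = np.where(mask, 1.0 / (v + tau2[:, None]), 0.0)
    sws = ws.sum(axis=1)
    pooled = np.einsum("ij,ij->i", ws, np.where(mask, y, 0.0)) / sws
    se = sws ** -0.5
    z = pooled / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    with np.errstate(invalid="ignore", divide="ignore"):
        i2 = np.where(q > 0, np.maximum(0.0, (q - (k - 1)) / q), 0.0)
    return pooled, se, tau2, q, i2, z, p, k


@dataclass
class MetaResult:
    """Pooled per-gene table plus the aligned per-study inputs.

    ``table`` has one row per evaluated gene; ``effects`` and ``variances``
    are gene x study frames (NaN = gene not measured in that study) kept so
    that leave-one-out reruns and forest/funnel exports can be recomputed.
    """

    table: pd.DataFrame
    effects: pd.DataFrame
    variances: pd.DataFrame
    config: MetaConfig = field(default_factory=MetaConfig)

    def gene(self, gene_id: str) -> pd.Series:
        return self.table.loc[gene_id]

    def study_inputs(self, gene_id: str) -> tuple[pd.Series, pd.Series]:
        y = self.effects.loc[gene_id].dropna()
        v = self.variances.loc[gene_id].dropna()
        return y, v

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format="%.10g")


def run_meta(dge_results: list[DGEResult], config: MetaConfig | None = None) -> MetaResult:
    """Pool per-study DGE tables into a per-gene meta-analysis table.

    Every gene measured in at least ``config.min_presence`` studies is
    evaluated with :func:`dl_pool`; pooled p-values are BH-adjusted across
    all evaluated genes; the ``significant`` flag applies the FDR, effect
    size and study-coverage filters. Rows are sorted by FDR ascending, then
    |pooled| descending.
    """
    config = config or MetaConfig()
    if len(dge_results) < 2:
        raise ValidationError("meta-analysis requires >= 2 studies")
    ids = [r.study_id for r in dge_results]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate study IDs")

    effects = pd.DataFrame({r.study_id: r.table["log2fc"] for r in dge_results})
    ses = pd.DataFrame({r.study_id: r.table["se"] for r in dge_results})
    variances = ses ** 2

    present = effects.notna().sum(axis=1)
    keep = present >= config.min_presence
    if not keep.any():
        raise ValidationError(
            f"no gene measured in >= {config.min_presence} studies"
        )
    effects, variances = effects.loc[keep], variances.loc[keep]

    pooled, se, tau2, q, i2, z, p, k = _dl_pool_matrix(
        effects.to_numpy(), variances.to_numpy()
    )
    fdr = bh_adjust(p)
    table = pd.DataFrame(
        {
            "k": k,
            "log2fc": pooled,
            "se": se,
            "ci_low": pooled - Z95 * se,
            "ci_high": pooled + Z95 * se,
            "z": z,
            "p": p,
            "fdr": fdr,
            "q_stat": q,
            "tau2": tau2,
            "i2": i2,
        },
        index=effects.index,
    )
    table["significant"] = (
        (table["fdr"] < config.fdr_max)
        & (table["log2fc"].abs() > config.lfc_min)
        & (table["k"] >= config.min_studies)
    )
    order = np.lexsort((-table["log2fc"].abs().to_numpy(), table["fdr"].to_numpy()))
    table = table.iloc[order]
    result = MetaResult(
        table=table,
        effects=effects.loc[table.index],
        variances=variances.loc[table.index],
        config=config,
    )
    result.table["loo_stable"] = _loo_flags(result)
    return result


def _loo_flags(result: MetaResult) -> pd.Series:
    flags = pd.Series(False, index=result.table.index)
    sig = result.table.index[result.table["significant"]]
    for gene in sig:
        y, v = result.study_inputs(gene)
        flags.loc[gene] = loo_sensitivity(y.to_numpy(), v.to_numpy(), result.config)[1]
    return flags


def loo_sensitivity(
    effects, variances, config: MetaConfig | None = None
) -> tuple[pd.DataFrame, bool]:
    """Leave-one-out re-pooling of a single gene.

    Returns the k re-pooled rows (one per omitted study) and a stability
    flag: stable iff every rerun keeps the sign of the full pooled effect,
    |pooled| above ``lfc_min`` and unadjusted p below ``fdr_max``.
    """
    config = config or MetaConfig()
    y = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    if y.size < 2:
        raise ValidationError("leave-one-out requires k >= 2 studies")
    full = dl_pool(y, v)
    rows = []
    for j in range(y.size):
        sub = dl_pool(np.delete(y, j), np.delete(v, j))
        rows.append(
            {
                "omitted": j,
                "pooled": sub.pooled,
                "se": sub.se,
                "tau2": sub.tau2,
                "p": sub.p,
                "ci_low": sub.ci_low,
                "ci_high": sub.ci_high,
            }
        )
    reruns = pd.DataFrame(rows).set_index("omitted")
    stable = bool(
        (np.sign(reruns["pooled"]) == np.sign(full.pooled)).all()
        and (reruns["pooled"].abs() > config.lfc_min).all()
        and (reruns["p"] < config.fdr_max).all()
    )
    return reruns, stable


def forest_funnel_data(result: MetaResult, gene_id: str) -> dict:
    """Plot-ready forest and funnel records for one evaluated gene.

    Forest: per-study effect with 95% CI from sqrt(v_j), plus the pooled
    diamond. Funnel: (effect, SE) points with the pseudo-confidence cone
    (half-width 1.96 * SE) centered at the pooled estimate.
    """
    y, v = result.study_inputs(gene_id)
    se_j = np.sqrt(v.to_numpy())
    row = result.table.loc[gene_id]
    forest = [
        {
            "study": s,
            "effect": float(yy),
            "ci_low": float(yy - Z95 * ss),
            "ci_high": float(yy + Z95 * ss),
            "weight": float(1.0 / (vv + row["tau2"])),
        }
        for s, yy, ss, vv in zip(y.index, y.to_numpy(), se_j, v.to_numpy())
    ]
    pooled = {
        "effect": float(row["log2fc"]),
        "ci_low": float(row["ci_low"]),
        "ci_high": float(row["ci_high"]),
    }
    max_se = float(se_j.max())
    cone_se = np.linspace(0.0, max_se * 1.05, 25)
    funnel = {
        "points": [
            {"effect": float(yy), "se": float(ss)} for yy, ss in zip(y.to_numpy(), se_j)
        ],
        "center": float(row["log2fc"]),
        "cone": [
            {
                "se": float(s),
                "low": float(row["log2fc"] - Z95 * s),
                "high": float(row["log2fc"] + Z95 * s),
            }
            for s in cone_se
        ],
    }
    return {"gene": gene_id, "forest": forest, "pooled": pooled, "funnel": funnel}
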