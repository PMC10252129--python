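"""Synthetic multi-study expression compendia and survival cohorts.

The generator emulates the statistical structure of a multi-study PDAC-like
compendium: ~21 studies of mixed platform (arrays with Gaussian log2
intensities, RNA-seq with negative-binomial counts), 320 control / 602 case
samples in total, incomplete per-study gene coverage, and per-gene
between-study heterogeneity following exactly the random-effects model the
DerSimonian–Laird estimator assumes: each study's true case-vs-control
log2 shift is delta_gj ~ Normal(mu_g, tau_g^2). A separate generator builds
a survival cohort whose hazard depends on a latent risk class expressed
through a gene signature. Ground truth is recorded in a manifest so that
parameter-recovery and calibration tests can score the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    ARRAY,
    CASE,
    CONTROL,
    NORMALIZED_LOG2,
    RAW_COUNTS,
    RNASEQ,
    ExpressionStudy,
    ValidationError,
)


def compendium_sample_sizes(n_studies: int = 21) -> list[tuple[int, int]]:
    """Per-study (n_control, n_case) sizes totalling 320 / 602 at 21 studies.

    Sizes are spread as evenly as integer arithmetic allows; every group has
    at least five samples (the compendium's inclusion rule).
    """
    total_control, total_case = 320, 602
    if n_studies != 21:
        total_control = max(5 * n_studies, round(320 / 21 * n_studies))
        total_case = max(5 * n_studies, round(602 / 21 * n_studies))
    base_c, rem_c = divmod(total_control, n_studies)
    base_t, rem_t = divmod(total_case, n_studies)
    controls = [base_c + 1 if i < rem_c else base_c for i in range(n_studies)]
    cases = [base_t + 1 if i < rem_t else base_t for i in range(n_studies)]
    return list(zip(controls, cases))


def default_platform_mix(n_studies: int = 21) -> list[str]:
    """19 array-like studies and 2 count-based studies at the default size."""
    n_rnaseq = 2 if n_studies >= 3 else 0
    return [ARRAY] * (n_studies - n_rnaseq) + [RNASEQ] * n_rnaseq


@dataclass
class SimulationConfig:
    """Knobs of the multi-study generator (all log2-scale where applicable)."""

    n_studies: int = 21
    n_genes: int = 2000
    de_fraction: float = 0.1
    effect_size_mean: float = 1.0
    tau: float = 0.2
    coverage_fraction: float = 0.5
    core_fraction: float = 0.1
    sample_sizes: list[tuple[int, int]] | None = None
    platform_mix: list[str] | None = None
    noise_sd: float = 0.8
    nb_dispersion: float = 0.1
    mean_library_size: float = 1e6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies <= 0 or self.n_genes <= 0:
            raise ValidationError("counts must be positive")
        if not 0 <= self.de_fraction <= 1:
            raise ValidationError("de_fraction must lie in [0, 1]")
        if not 0 < self.coverage_fraction <= 1:
            raise ValidationError("coverage_fraction must lie in (0, 1]")
        if not 0 <= self.core_fraction <= 1:
            raise ValidationError("core_fraction must lie in [0, 1]")
        if self.tau < 0 or self.noise_sd <= 0 or self.nb_dispersion < 0:
            raise ValidationError("tau >= 0, noise_sd > 0, nb_dispersion >= 0 required")
        if self.sample_sizes is None:
            self.sample_sizes = compendium_sample_sizes(self.n_studies)
        if len(self.sample_sizes) != self.n_studies:
            raise ValidationError("one (n_control, n_case) pair per study required")
        for nc, nt in self.sample_sizes:
            if nc < 5 or nt < 5:
                raise ValidationError("each group needs >= 5 samples")
        if self.platform_mix is None:
            self.platform_mix = default_platform_mix(self.n_studies)
        if len(self.platform_mix) != self.n_studies:
            raise ValidationError("one platform label per study required")
        if not set(self.platform_mix) <= {ARRAY, RNASEQ}:
            raise ValidationError("platforms must be 'array' or 'rnaseq'")


@dataclass
class TruthManifest:
    """Ground truth of a simulation run.

    ``mu`` and ``tau_g`` give each gene's true mean effect and heterogeneity
    SD (log2 units); ``de`` flags genes with mu != 0; ``coverage`` is the
    study x gene measurement mask and ``study_effects`` the realized
    delta_gj (NaN where unmeasured). Survival truth is populated by
    :func:`simulate_survival_cohort`.
    """

    mu: pd.Series | None = None
    tau_g: pd.Series | None = None
    de: pd.Series | None = None
    coverage: pd.DataFrame | None = None
    study_effects: pd.DataFrame | None = None
    orphan_genes: list[str] = field(default_factory=list)
    survival: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "mu": None if self.mu is None else self.mu.to_dict(),
            "tau_g": None if self.tau_g is None else self.tau_g.to_dict(),
            "de": None if self.de is None else {k: bool(v) for k, v in self.de.items()},
            "coverage": None
            if self.coverage is None
            else {s: [int(b) for b in row] for s, row in self.coverage.iterrows()},
            "coverage_genes": None if self.coverage is None else list(self.coverage.columns),
            "study_effects": None
            if self.study_effects is None
            else {
                s: {g: (None if not np.isfinite(x) else float(x)) for g, x in row.items()}
                for s, row in self.study_effects.iterrows()
            },
            "orphan_genes": self.orphan_genes,
            "survival": self.survival,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            d = json.load(fh)
        coverage = None
        if d.get("coverage") is not None:
            coverage = pd.DataFrame.from_dict(d["coverage"], orient="index")
            coverage.columns = d["coverage_genes"]
            coverage = coverage.astype(bool)
        effects = None
        if d.get("study_effects") is not None:
            effects = pd.DataFrame.from_dict(d["study_effects"], orient="index").astype(float)
        return cls(
            mu=None if d.get("mu") is None else pd.Series(d["mu"], dtype=float),
            tau_g=None if d.get("tau_g") is None else pd.Series(d["tau_g"], dtype=float),
            de=None if d.get("de") is None else pd.Series(d["de"], dtype=bool),
            coverage=coverage,
            study_effects=effects,
            orphan_genes=d.get("orphan_genes", []),
            survival=d.get("survival", {}),
        )


def _gene_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{i:0{width}d}" for i in range(n)]


def simulate_multistudy(config: SimulationConfig) -> tuple[list[ExpressionStudy], TruthManifest]:
    """Generate a multi-study compendium with recorded ground truth.

    A hierarchical seed stream gives each study its own independent RNG, so
    adding studies never reshuffles earlier ones. Array studies carry
    Gaussian log2 intensities with a case shift delta_gj ~ N(mu_g, tau_g^2);
    RNA-seq studies carry negative-binomial counts whose log2 mean ratio is
    that same delta_gj. Each study measures a random ``coverage_fraction``
    subset of genes, except an always-measured core set.
    """
    ss = np.random.SeedSequence(config.seed)
    truth_rng = np.random.default_rng(ss.spawn(1)[0])
    study_seeds = ss.spawn(1 + config.n_studies)[1:]

    genes = _gene_ids(config.n_genes)
    g = config.n_genes
    n_de = int(round(config.de_fraction * g))
    de_idx = truth_rng.choice(g, size=n_de, replace=False)
    signs = truth_rng.choice([-1.0, 1.0], size=n_de)
    mu = np.zeros(g)
    mu[de_idx] = signs * config.effect_size_mean
    tau_g = np.zeros(g)
    tau_g[de_idx] = config.tau
    baseline = truth_rng.normal(7.0, 1.5, size=g)  # log2 mean intensity
    n_core = int(round(config.core_fraction * g))
    core = np.zeros(g, dtype=bool)
    if n_core:
        core[truth_rng.choice(g, size=n_core, replace=False)] = True

    studies: list[ExpressionStudy] = []
    coverage_rows = []
    effect_rows = []
    for j in range(config.n_studies):
        rng = np.random.default_rng(study_seeds[j])
        study_id = f"SYN{j:03d}"
        nc, nt = config.sample_sizes[j]
        platform = config.platform_mix[j]

        measured = rng.random(g) < config.coverage_fraction
        measured |= core
        delta = np.where(
            tau_g > 0, rng.normal(mu, np.where(tau_g > 0, tau_g, 1.0)), mu
        )
        coverage_rows.append(measured.copy())
        effect_rows.append(np.where(measured, delta, np.nan))

        sample_ids = [f"{study_id}_C{i}" for i in range(nc)] + [
            f"{study_id}_T{i}" for i in range(nt)
        ]
        groups = [CONTROL] * nc + [CASE] * nt
        sheet = pd.DataFrame({"group": groups}, index=pd.Index(sample_ids, name="sample_id"))

        gm = np.array(genes)[measured]
        b = baseline[measured]
        d = delta[measured]
        if platform == ARRAY:
            means = np.concatenate(
                [np.tile(b[:, None], (1, nc)), np.tile((b + d)[:, None], (1, nt))], axis=1
            )
            mat = means + rng.normal(0.0, config.noise_sd, size=means.shape)
            matrix = pd.DataFrame(mat, index=gm, columns=sample_ids)
            state = NORMALIZED_LOG2
        else:
            # gene relative abundances from the baseline intensities
            q = 2.0 ** b
            q = q / q.sum()
            libs = rng.lognormal(
                mean=np.log(config.mean_library_size), sigma=0.3, size=nc + nt
            )
            fold = 2.0 ** d
            mean_ctrl = q
            mean_case = q * fold
            mean_case = mean_case / mean_case.sum()
            cols = []
            for s in range(nc + nt):
                rel = mean_ctrl if s < nc else mean_case
                m = rel * libs[s]
                if config.nb_dispersion > 0:
                    shape = 1.0 / config.nb_dispersion
                    lam = rng.gamma(shape, m / shape)
                else:
                    lam = m
                cols.append(rng.poisson(lam))
            matrix = pd.DataFrame(
                np.column_stack(cols).astype(np.int64), index=gm, columns=sample_ids
            )
            state = RAW_COUNTS
        studies.append(
            ExpressionStudy(
                study_id=study_id,
                matrix=matrix,
                samples=sheet,
                platform=platform,
                normalization_state=state,
            )
        )

    coverage = pd.DataFrame(
        np.vstack(coverage_rows), index=[s.study_id for s in studies], columns=genes
    )
    effects = pd.DataFrame(
        np.vstack(effect_rows), index=[s.study_id for s in studies], columns=genes
    )
    orphans = [genes[i] for i in np.flatnonzero(coverage.sum(axis=0).to_numpy() == 0)]
    manifest = TruthManifest(
        mu=pd.Series(mu, index=genes),
        tau_g=pd.Series(tau_g, index=genes),
        de=pd.Series(mu != 0, index=genes),
        coverage=coverage,
        study_effects=effects,
        orphan_genes=orphans,
    )
    return studies, manifest


# ---------------------------------------------------------------------------
# Survival cohort
# ---------------------------------------------------------------------------

def simulate_survival_cohort(
    n_samples: int = 180,
    signature_size: int = 28,
    n_noise_genes: int = 72,
    hazard_ratio: float = 2.36,
    baseline_rate: float = 1.0 / 30.0,
    censoring_rate: float = 0.01,
    expression_shift: float = 1.5,
    high_risk_fraction: float = 0.5,
    seed: int = 0,
):
    """Survival cohort whose hazard depends on a gene-signature risk class.

    Half the samples (by default) belong to a latent high-risk class whose
    hazard is ``baseline_rate * hazard_ratio``; event times are exponential
    with independent exponential censoring. Signature genes are shifted by
    ``expression_shift`` SD units in high-risk samples before z-scoring, so
    the quartile/count signature procedure can recover the latent class.

    Returns (cohort, manifest); the manifest's ``survival`` dict records the
    latent labels, signature genes, and generative rates.
    """
    from .survival import SurvivalCohort, zscore_matrix

    if n_samples < 8:
        raise ValidationError("need >= 8 samples")
    if hazard_ratio <= 0 or baseline_rate <= 0:
        raise ValidationError("rates must be positive")
    if censoring_rate < 0:
        raise ValidationError("censoring_rate must be >= 0")

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    n_high = int(round(high_risk_fraction * n_samples))
    labels = np.zeros(n_samples, dtype=int)
    labels[rng.choice(n_samples, size=n_high, replace=False)] = 1

    sample_ids = [f"P{i:04d}" for i in range(n_samples)]
    sig_genes = [f"SIG{i:03d}" for i in range(signature_size)]
    noise_genes = [f"NSE{i:03d}" for i in range(n_noise_genes)]

    sig = rng.normal(0.0, 1.0, size=(signature_size, n_samples))
    sig += expression_shift * labels[None, :]
    noise = rng.normal(0.0, 1.0, size=(n_noise_genes, n_samples))
    expr = pd.DataFrame(
        np.vstack([sig, noise]), index=sig_genes + noise_genes, columns=sample_ids
    )
    z = zscore_matrix(expr)

    rate = baseline_rate * np.where(labels == 1, hazard_ratio, 1.0)
    event_time = rng.exponential(1.0 / rate)
    if censoring_rate > 0:
        censor_time = rng.exponential(1.0 / censoring_rate, size=n_samples)
    else:
        censor_time = np.full(n_samples, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    time = np.maximum(time, 1e-9)  # strictly positive

    table = pd.DataFrame(
        {"time": time, "event": event, "risk_class": labels},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    cohort = SurvivalCohort(table=table[["time", "event"]].copy(), expression=z)
    manifest = TruthManifest(
        survival={
            "labels": {s: int(l) for s, l in zip(sample_ids, labels)},
            "signature_genes": sig_genes,
            "hazard_ratio": hazard_ratio,
            "baseline_rate": baseline_rate,
            "censoring_rate": censoring_rate,
            "expression_shift": expression_shift,
        }
    )
    return cohort, manifest


# ---------------------------------------------------------------------------
# Gene sets with known enrichment (pipeline plumbing)
# ---------------------------------------------------------------------------

def make_gene_sets(
    manifest: TruthManifest,
    n_sets: int = 40,
    set_size: int = 40,
    n_enriched: int = 3,
    enriched_de_fraction: float = 0.6,
    seed: int = 0,
):
    """Random gene sets over the simulated genes, a few enriched for DE genes.

    Returns a :class:`~txmeta.enrichment.GeneSetCollection`; useful to give
    the pipeline's ORA stage a collection with known positives.
    """
    from .enrichment import GeneSetCollection

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
    genes = np.array(manifest.mu.index)
    de = manifest.de.to_numpy()
    de_genes, null_genes = genes[de], genes[~de]
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for i in range(n_sets):
        name = f"SET{i:03d}"
        if i < n_enriched and len(de_genes):
            n_from_de = min(int(round(enriched_de_fraction * set_size)), len(de_genes))
            pick = np.concatenate(
                [
                    rng.choice(de_genes, size=n_from_de, replace=False),
                    rng.choice(null_genes, size=set_size - n_from_de, replace=False),
                ]
            )
            descriptions[name] = "enriched"
        else:
            pick = rng.choice(genes, size=min(set_size, len(genes)), replace=False)
            descriptions[name] = "random"
        sets[name] = set(pick.tolist())
    return GeneSetCollection(sets=sets, descriptions=descriptions)
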