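import numpy as np
import pandas as pd
import pytest

from txmeta import ExpressionStudy, MetaConfig, SimulationConfig, simulate_multistudy
from txmeta.containers import CASE, CONTROL
from txmeta.preprocess import fit_dge, normalize_study
from txmeta.survival import SurvivalCohort


def make_array_study(values, n_control, n_case, study_id="S1", pair_ids=None):
    """Build a small normalized array study from a gene x sample array."""
    values = np.asarray(values, dtype=float)
    genes = [f"g{i}" for i in range(values.shape[0])]
    samples = [f"{study_id}_s{i}" for i in range(values.shape[1])]
    groups = [CONTROL] * n_control + [CASE] * n_case
    sheet = pd.DataFrame({"group": groups}, index=pd.Index(samples, name="sample_id"))
    if pair_ids is not None:
        sheet["pair_id"] = pair_ids
    return ExpressionStudy(
        study_id=study_id,
        matrix=pd.DataFrame(values, index=genes, columns=samples),
        samples=sheet,
    )


@pytest.fixture(scope="session")
def small_compendium():
    """Three small mixed-platform studies with ground truth."""
    cfg = SimulationConfig(
        n_studies=3,
        n_genes=200,
        de_fraction=0.1,
        coverage_fraction=0.9,
        sample_sizes=[(8, 10), (9, 12), (10, 10)],
        platform_mix=["array", "array", "rnaseq"],
        seed=42,
    )
    return simulate_multistudy(cfg)


@pytest.fixture(scope="session")
def small_meta(small_compendium):
    from txmeta import run_meta

    studies, truth = small_compendium
    dges = [fit_dge(normalize_study(s)) for s in studies]
    return run_meta(dges, MetaConfig(min_studies=3, min_presence=2)), truth


@pytest.fixture()
def toy_cohort():
    """Deterministic 12-sample cohort with a 4-gene z-score matrix."""
    rng = np.random.default_rng(7)
    samples = [f"p{i}" for i in range(12)]
    table = pd.DataFrame(
        {
            "time": [3, 5, 7, 2, 11, 13, 17, 19, 23, 29, 31, 37],
            "event": [1, 1, 0, 1, 1, 0, 1, 1, 1, 0, 1, 1],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    expr = pd.DataFrame(
        rng.normal(size=(4, 12)), index=[f"g{i}" for i in range(4)], columns=samples
    )
    from txmeta.survival import zscore_matrix

    return SurvivalCohort(table=table, expression=zscore_matrix(expr))
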