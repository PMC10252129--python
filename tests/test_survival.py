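"""Tests for quartile groups, KM, log-rank, Cox and the risk-score signature."""

import numpy as np
import pandas as pd
import pytest

from txmeta import (
    SurvivalCohort,
    cooccurrence_groups,
    cox_fit,
    km_estimate,
    logrank_test,
    quartile_groups,
    signature_score,
    simulate_survival_cohort,
    zscore_matrix,
)
from txmeta.containers import ValidationError
from txmeta.survival import cox_score_test, jaccard_matrix


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def logrank_oracle(ta, ea, tb, eb):
    """Log-rank by explicit 2x2 risk-table enumeration at every event time."""
    ta, ea = np.asarray(ta, float), np.asarray(ea, int)
    tb, eb = np.asarray(tb, float), np.asarray(eb, int)
    times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_minus_e, var = 0.0, 0.0
    for t in times:
        na = (ta >= t).sum()
        nb = (tb >= t).sum()
        n = na + nb
        da = ((ta == t) & (ea == 1)).sum()
        db = ((tb == t) & (eb == 1)).sum()
        d = da + db
        if n < 2 or d == 0:
            continue
        e_a = d * na / n
        v = d * (na / n) * (nb / n) * (n - d) / (n - 1)
        o_minus_e += da - e_a
        var += v
    return o_minus_e ** 2 / var


def km_oracle(times, events):
    """Product-limit S(t) evaluated by hand at each distinct event time."""
    times, events = np.asarray(times, float), np.asarray(events, int)
    s = 1.0
    out = {}
    for t in np.unique(times[events == 1]):
        n = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1 - d / n
        out[t] = s
    return out


# ---------------------------------------------------------------------------
# z-scores and quartile groups
# ---------------------------------------------------------------------------

class TestZScore:
    def test_rows_standardized(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame(rng.normal(5, 3, size=(6, 20)))
        z = zscore_matrix(x)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z.std(axis=1, ddof=1), 1, atol=1e-9)

    def test_hand_case(self):
        z = zscore_matrix(pd.DataFrame([[1.0, 2.0, 3.0]]))
        assert np.allclose(z.to_numpy()[0], [-1, 0, 1])

    def test_constant_gene_dropped(self):
        x = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"])
        z = zscore_matrix(x)
        assert list(z.index) == ["ok"]
        with pytest.raises(ValidationError):
            zscore_matrix(pd.DataFrame([[2.0, 2.0, 2.0]]))


class TestQuartileGroups:
    def test_values_one_to_eight(self):
        s = pd.Series(np.arange(1.0, 9.0), index=list("abcdefgh"))
        low, high = quartile_groups(s)
        assert set(low) == {"a", "b"}
        assert set(high) == {"g", "h"}

    def test_180_distinct_values_give_45_45(self):
        rng = np.random.default_rng(1)
        s = pd.Series(rng.permutation(np.linspace(-3, 3, 180)))
        low, high = quartile_groups(s)
        assert len(low) == 45
        assert len(high) == 45

    def test_degenerate_distribution_rejected(self):
        s = pd.Series(np.ones(16), name="gX")
        with pytest.raises(ValidationError, match="gX"):
            quartile_groups(s)


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

class TestKM:
    def test_all_censored_flat_at_one(self):
        km = km_estimate([1, 2, 3, 4], [0, 0, 0, 0])
        assert np.allclose(km["survival"], 1.0)

    def test_no_censoring_equals_empirical_survival(self):
        km = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        steps = km.set_index("time")["survival"]
        assert steps.loc[1.0] == pytest.approx(0.75)
        assert steps.loc[2.0] == pytest.approx(0.5)
        assert steps.loc[3.0] == pytest.approx(0.25)
        assert steps.loc[4.0] == pytest.approx(0.0)

    def test_censoring_fixture_product_limit(self):
        # times (1, 2+, 3, 4): S = 3/4 after t=1, 3/4 * 1/2 after t=3, 0 after 4
        km = km_estimate([1, 2, 3, 4], [1, 0, 1, 1]).set_index("time")["survival"]
        assert km.loc[1.0] == pytest.approx(0.75)
        assert km.loc[3.0] == pytest.approx(0.375)
        assert km.loc[4.0] == pytest.approx(0.0)

    def test_matches_hand_oracle_on_random_data(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(1.0, 60)
        e = (rng.random(60) < 0.7).astype(int)
        km = km_estimate(t, e).set_index("time")["survival"]
        for tt, ss in km_oracle(t, e).items():
            assert km.loc[tt] == pytest.approx(ss, abs=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([-1, 2], [1, 1])


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

class TestLogrank:
    # clear group difference: the chi-square p is checked against the exact
    # permutation law, which it approximates well in the tail
    FIXTURE_A = ([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], [1, 1, 1, 1, 1, 1])
    FIXTURE_B = ([4.0, 6.0, 8.0, 10.0, 12.0, 14.0], [1, 1, 0, 1, 1, 0])

    def test_identical_groups_statistic_zero(self):
        g = ([1.0, 2.0, 3.0], [1, 1, 0])
        stat, df, p = logrank_test(g, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_risk_table_enumeration_oracle(self):
        stat, df, p = logrank_test(self.FIXTURE_A, self.FIXTURE_B)
        expected = logrank_oracle(*self.FIXTURE_A, *self.FIXTURE_B)
        assert df == 1
        assert stat == pytest.approx(expected, abs=1e-9)

    def test_p_close_to_permutation_reference(self):
        """Chi-square p agrees with a 10,000-shuffle permutation distribution."""
        ta, ea = np.array(self.FIXTURE_A[0]), np.array(self.FIXTURE_A[1])
        tb, eb = np.array(self.FIXTURE_B[0]), np.array(self.FIXTURE_B[1])
        obs = logrank_oracle(ta, ea, tb, eb)
        t = np.concatenate([ta, tb])
        e = np.concatenate([ea, eb])
        rng = np.random.default_rng(12345)
        n_a = len(ta)
        hits = 0
        for _ in range(10_000):
            idx = rng.permutation(len(t))
            a, b = idx[:n_a], idx[n_a:]
            if logrank_oracle(t[a], e[a], t[b], e[b]) >= obs - 1e-12:
                hits += 1
        p_perm = hits / 10_000
        _, _, p_chi2 = logrank_test((ta, ea), (tb, eb))
        assert abs(p_chi2 - p_perm) <= 0.02

    def test_symmetry_and_time_rescaling(self):
        s1, _, p1 = logrank_test(self.FIXTURE_A, self.FIXTURE_B)
        s2, _, p2 = logrank_test(self.FIXTURE_B, self.FIXTURE_A)
        assert s1 == pytest.approx(s2, rel=1e-12)
        scaled_a = ([x * 3.5 for x in self.FIXTURE_A[0]], self.FIXTURE_A[1])
        scaled_b = ([x * 3.5 for x in self.FIXTURE_B[0]], self.FIXTURE_B[1])
        s3, _, _ = logrank_test(scaled_a, scaled_b)
        assert s3 == pytest.approx(s1, rel=1e-12)

    def test_validation(self):
        with pytest.raises(ValidationError):
            logrank_test(([], []), ([1.0], [1]))
        with pytest.raises(ValidationError):
            logrank_test(([1.0], [0]), ([2.0], [0]))


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------

class TestCox:
    def test_null_covariate_near_zero(self):
        rng = np.random.default_rng(5)
        n = 400
        t = rng.exponential(1.0, n)
        df = pd.DataFrame(
            {"time": t, "event": 1, "x": rng.normal(size=n)},
            index=[f"s{i}" for i in range(n)],
        )
        fit = cox_fit(df[["time", "event"]], df[["x"]])
        assert abs(fit.summary.loc["x", "coef"]) < 3 * fit.summary.loc["x", "se"]

    def test_recovers_known_hazard_ratio(self):
        rng = np.random.default_rng(6)
        n = 2000
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(1.0 / (0.05 * 2.0 ** x))
        c = rng.exponential(1.0 / 0.005, n)
        df = pd.DataFrame(
            {"time": np.minimum(t, c), "event": (t <= c).astype(int), "x": x},
            index=[f"s{i}" for i in range(n)],
        )
        fit = cox_fit(df[["time", "event"]], df[["x"]])
        assert fit.converged
        assert 1.8 <= fit.summary.loc["x", "hr"] <= 2.2

    def test_matches_lifelines_on_tie_free_data(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(7)
        n = 120
        df = pd.DataFrame(
            {
                "time": rng.exponential(1.0, n),
                "event": (rng.random(n) < 0.8).astype(int),
                "x1": rng.normal(size=n),
                "x2": (rng.random(n) < 0.4).astype(float),
            },
            index=[f"s{i}" for i in range(n)],
        )
        fit = cox_fit(df[["time", "event"]], df[["x1", "x2"]])
        cph = CoxPHFitter().fit(df, "time", "event")
        for cov in ("x1", "x2"):
            assert fit.summary.loc[cov, "coef"] == pytest.approx(cph.params_[cov], abs=1e-5)
            assert fit.summary.loc[cov, "se"] == pytest.approx(
                cph.standard_errors_[cov], abs=1e-5
            )

    def test_score_test_equals_logrank_without_ties(self):
        rng = np.random.default_rng(8)
        n = 50
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(1.0, n) * np.where(x == 1, 0.6, 1.0)
        e = np.ones(n, dtype=int)
        stat, _ = cox_score_test(t, e, x)
        lr_stat, _, _ = logrank_test((t[x == 1], e[x == 1]), (t[x == 0], e[x == 0]))
        assert abs(stat - lr_stat) / lr_stat < 1e-6

    def test_breslow_equals_efron_without_ties(self):
        rng = np.random.default_rng(9)
        n = 60
        df = pd.DataFrame(
            {
                "time": rng.exponential(1.0, n),
                "event": (rng.random(n) < 0.7).astype(int),
                "x": rng.normal(size=n),
            },
            index=[f"s{i}" for i in range(n)],
        )
        b = cox_fit(df[["time", "event"]], df[["x"]], ties="breslow")
        e = cox_fit(df[["time", "event"]], df[["x"]], ties="efron")
        assert b.summary.loc["x", "coef"] == pytest.approx(e.summary.loc["x", "coef"], abs=1e-8)

    def test_fewer_events_than_covariates_rejected(self):
        df = pd.DataFrame(
            {"time": [1.0, 2.0, 3.0], "event": [0, 0, 1], "x1": [0, 1, 0], "x2": [1, 0, 1]},
            index=["a", "b", "c"],
        )
        with pytest.raises(ValidationError):
            cox_fit(df[["time", "event"]], df[["x1", "x2"]])


# ---------------------------------------------------------------------------
# signature score
# ---------------------------------------------------------------------------

def _cohort_with_counts(counts):
    """Build a cohort whose signature indicator column sums equal ``counts``.

    Every gene is made highly expressed (above its Q3) in exactly two
    samples, assigned greedily to the samples with the largest remaining
    need, so the per-sample counts land exactly on the requested values.
    """
    counts = np.asarray(counts, dtype=int)
    n = len(counts)
    assert counts.sum() % 2 == 0
    n_genes = counts.sum() // 2
    need = counts.copy()
    rows = []
    for _ in range(n_genes):
        top2 = np.argsort(-need, kind="mergesort")[:2]
        row = np.zeros(n)
        row[top2] = 1
        need[top2] -= 1
        rows.append(row)
    assert (need == 0).all()
    indicator = np.array(rows)
    rng = np.random.default_rng(0)
    base = rng.uniform(-1, 0, size=indicator.shape)
    expr = np.where(indicator == 1, 10.0 + rng.uniform(0, 1, indicator.shape), base)
    samples = [f"p{i}" for i in range(n)]
    table = pd.DataFrame(
        {"time": np.arange(1.0, n + 1.0), "event": 1},
        index=pd.Index(samples, name="sample_id"),
    )
    expression = pd.DataFrame(
        expr, index=[f"g{i}" for i in range(n_genes)], columns=samples
    )
    return SurvivalCohort(table=table, expression=expression)


class TestSignatureScore:
    def test_counts_and_median_cutoff_rule(self):
        # per-sample counts (8,7,6,6,6,5,4,2): median 6 -> "at least six" = high
        cohort = _cohort_with_counts([8, 7, 6, 6, 6, 5, 4, 2])
        res = signature_score(cohort, list(cohort.expression.index))
        assert list(res.counts) == [8, 7, 6, 6, 6, 5, 4, 2]
        assert res.cutoff == 6.0
        assert list(res.risk) == ["high", "high", "high", "high", "high", "low", "low", "low"]

    def test_cutoff_three_count_three_is_high(self):
        cohort = _cohort_with_counts([6, 5, 4, 3, 3, 2, 2, 1])
        res = signature_score(cohort, list(cohort.expression.index))
        assert res.cutoff == 3.0
        assert res.risk.iloc[3] == "high"  # count exactly at the median

    def test_sample_high_on_all_genes_is_high_risk(self):
        rng = np.random.default_rng(1)
        samples = [f"p{i}" for i in range(9)]
        expr = pd.DataFrame(
            rng.uniform(-1, 1, size=(5, 9)), index=[f"g{i}" for i in range(5)], columns=samples
        )
        expr["p0"] = 10.0
        table = pd.DataFrame(
            {"time": np.arange(1.0, 10.0), "event": 1},
            index=pd.Index(samples, name="sample_id"),
        )
        res = signature_score(SurvivalCohort(table=table, expression=expr), list(expr.index))
        assert res.counts["p0"] == 5
        assert res.risk["p0"] == "high"

    def test_invariant_to_gene_order_and_monotone_transform(self):
        cohort, truth = simulate_survival_cohort(n_samples=60, signature_size=6, seed=3)
        genes = truth.survival["signature_genes"]
        a = signature_score(cohort, genes)
        b = signature_score(cohort, genes[::-1])
        assert a.risk.equals(b.risk)
        warped = SurvivalCohort(
            table=cohort.table.copy(),
            expression=np.tanh(cohort.expression / 3.0) * 5.0,  # strictly monotone
        )
        c = signature_score(warped, genes)
        assert a.risk.equals(c.risk)

    def test_recovers_latent_risk_groups(self):
        cohort, truth = simulate_survival_cohort(n_samples=240, hazard_ratio=2.5, seed=11)
        res = signature_score(cohort, truth.survival["signature_genes"], cox=True)
        assert res.logrank[2] < 0.01
        med_high = _km_median(res.km["high"])
        med_low = _km_median(res.km["low"])
        assert med_high < med_low

    def test_missing_genes_dropped_and_empty_rejected(self, toy_cohort):
        res = signature_score(toy_cohort, ["g0", "g1", "nope"])
        assert set(res.genes) == {"g0", "g1"}
        with pytest.raises(ValidationError):
            signature_score(toy_cohort, ["nope"])


def _km_median(curve: pd.DataFrame) -> float:
    below = curve[curve["survival"] <= 0.5]
    return float(below["time"].iloc[0]) if len(below) else float("inf")


# ---------------------------------------------------------------------------
# co-occurrence
# ---------------------------------------------------------------------------

class TestCooccurrence:
    def test_disjoint_blocks_recovered(self):
        block_a = [1, 1, 1, 1, 0, 0, 0, 0]
        block_b = [0, 0, 0, 0, 1, 1, 1, 1]
        ind = pd.DataFrame(
            [block_a, block_a, block_a, block_b, block_b, block_b],
            index=["a1", "a2", "a3", "b1", "b2", "b3"],
        )
        out = cooccurrence_groups(ind, k=2)
        clusters = out["clusters"]
        assert len(set(clusters[["a1", "a2", "a3"]])) == 1
        assert len(set(clusters[["b1", "b2", "b3"]])) == 1
        assert clusters["a1"] != clusters["b1"]

    def test_duplicate_rows_jaccard_one_merged_first(self):
        ind = pd.DataFrame(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]], index=["d1", "d2", "other"]
        )
        out = cooccurrence_groups(ind, k=2)
        assert out["jaccard"].loc["d1", "d2"] == 1.0
        assert out["linkage"][0, 2] == pytest.approx(0.0)  # first merge at distance 0
        assert out["clusters"]["d1"] == out["clusters"]["d2"]

    def test_jaccard_matches_set_arithmetic(self):
        ind = pd.DataFrame(
            [[1, 0, 1, 1, 0], [1, 1, 0, 1, 0], [0, 0, 0, 1, 1], [1, 1, 1, 1, 1]],
            index=list("wxyz"),
        )
        jac = jaccard_matrix(ind)
        sets = {g: {i for i, v in enumerate(row) if v} for g, row in ind.iterrows()}
        for a in sets:
            for b in sets:
                expected = len(sets[a] & sets[b]) / len(sets[a] | sets[b])
                assert jac.loc[a, b] == pytest.approx(expected)

    def test_cooccurrence_counts(self):
        ind = pd.DataFrame([[1, 1, 0], [1, 0, 1]], index=["a", "b"])
        out = cooccurrence_groups(ind, k=1)
        assert out["cooccurrence"].loc["a", "b"] == 1
        assert out["cooccurrence"].loc["a", "a"] == 2

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            cooccurrence_groups(pd.DataFrame([[0, 0], [0, 0]], index=["a", "b"]))
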