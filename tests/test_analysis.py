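import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import mannwhitneyu

from csnq import analysis
from csnq.analysis import (
    correlation_table,
    fdr_adjust,
    rank_sum_test,
    regression_age_childcare,
    spearman_rho,
    sqrt_half_transform,
    summary_table,
)


class TestSpearman:
    def test_strictly_increasing(self):
        res = spearman_rho([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.value == pytest.approx(1.0)

    def test_strictly_decreasing(self):
        assert spearman_rho([1, 2, 3], [9, 5, 1]).value == pytest.approx(-1.0)

    def test_tied_ranks_average(self):
        # ranks x: 1, 2.5, 2.5, 4; ranks y: 1, 2, 3.5, 3.5 -> Pearson = 5/6
        res = spearman_rho([1, 2, 2, 4], [2, 3, 5, 5])
        assert res.value == pytest.approx(5 / 6)

    def test_listwise_deletion(self):
        res = spearman_rho([1, 2, np.nan, 4, 5], [2, 4, 9, np.nan, 10])
        assert res.n == 3

    def test_monotone_transform_invariance(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        y = np.array([2.0, 7.0, 1.0, 8.0, 0.5, 3.0])
        base = spearman_rho(x, y).value
        assert spearman_rho(np.exp(x), y).value == pytest.approx(base)
        assert spearman_rho(x, y**3).value == pytest.approx(base)


def bh_step_up(pvals):
    """Direct step-up enumeration: adj_(i) = min_{j >= i} m * p_(j) / j."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * pvals[idx] / rank)
        adj[idx] = running
    return adj


class TestFdrAdjust:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.03]) == pytest.approx([0.03])

    def test_all_equal_stay_equal(self):
        out = fdr_adjust([0.2, 0.2, 0.2])
        assert np.allclose(out, 0.2)

    def test_step_up_example(self):
        out = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_never_lowers_and_preserves_order(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 30))
            out = fdr_adjust(p)
            assert np.all(out >= p - 1e-15)
            assert np.all(out <= 1.0 + 1e-15)
            order = np.argsort(p)
            assert np.all(np.diff(out[order]) >= -1e-15)

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 25))
            assert np.allclose(fdr_adjust(p), bh_step_up(p), atol=1e-12)

    def test_nan_passthrough(self):
        out = fdr_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1]) and not np.isnan(out[0])


class TestSqrtHalfTransform:
    def test_values(self):
        assert sqrt_half_transform(0) == pytest.approx(math.sqrt(0.5))
        assert sqrt_half_transform(3.5) == pytest.approx(2.0)

    def test_strictly_increasing(self):
        x = np.sort(np.random.default_rng(0).uniform(0, 30, 50))
        assert np.all(np.diff(sqrt_half_transform(x)) > 0)


class TestRegression:
    def _frame(self, rng, n=120):
        age = rng.uniform(6, 60, n)
        care = rng.integers(0, 2, n).astype(bool)
        return age, care

    def test_noiseless_slope_recovered(self):
        rng = np.random.default_rng(1)
        age, care = self._frame(rng)
        # response constructed so that sqrt(size + 0.5) = 2 * age exactly
        df = pd.DataFrame(
            {
                "network_size": (2 * age) ** 2 - 0.5,
                "age_months": age,
                "childcare_out_of_home": care,
            }
        )
        out = regression_age_childcare(df)
        assert out["age_months"].value == pytest.approx(2.0)
        assert out["r_squared"].value == pytest.approx(1.0)
        assert abs(out["childcare"].value) < 1e-8

    def test_permuted_response_has_near_zero_r2(self):
        rng = np.random.default_rng(2)
        age, care = self._frame(rng, n=300)
        size = 3 + 0.2 * age + rng.normal(0, 3, 300)
        df = pd.DataFrame(
            {
                "network_size": rng.permutation(np.clip(size, 0, None)),
                "age_months": age,
                "childcare_out_of_home": care,
            }
        )
        out = regression_age_childcare(df)
        assert out["r_squared"].value < 0.05

    def test_interaction_null_p_uniform(self):
        """With no configured interaction, the interaction p-value should be
        roughly uniform: its rejection rate at alpha=0.2 stays near 0.2."""
        rng = np.random.default_rng(3)
        hits = 0
        reps = 200
        for _ in range(reps):
            age, care = self._frame(rng, n=80)
            # additive on the analysis (sqrt) scale, so the interaction is
            # a true null
            lin = 2.0 + 0.03 * age + 0.3 * care + rng.normal(0, 0.4, 80)
            df = pd.DataFrame(
                {
                    "network_size": np.clip(lin, 0.1, None) ** 2 - 0.5,
                    "age_months": age,
                    "childcare_out_of_home": care,
                }
            )
            if regression_age_childcare(df)["age_x_childcare"].p_value < 0.2:
                hits += 1
        se = math.sqrt(0.2 * 0.8 / reps)
        assert hits / reps < 0.2 + 3 * se

    def test_constant_predictor_named(self):
        df = pd.DataFrame(
            {
                "network_size": [5, 8, 11.0],
                "age_months": [10, 20, 30.0],
                "childcare_out_of_home": [True, True, True],
            }
        )
        with pytest.raises(ValueError, match="childcare"):
            regression_age_childcare(df)


def permutation_rank_sum_p(a, b):
    """Exhaustive permutation oracle over pooled value orderings."""
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = rankdata(pooled)
    mu = n_a * len(b) / 2.0
    w_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0
    extreme = total = 0
    for perm in itertools.permutations(range(len(pooled))):
        w = ranks[list(perm[:n_a])].sum() - n_a * (n_a + 1) / 2.0
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            extreme += 1
        total += 1
    return extreme / total


class TestRankSum:
    def test_identical_groups_p_one(self):
        res = rank_sum_test([1, 2, 3], [1, 2, 3], method="exact")
        assert res.p_value == pytest.approx(1.0)

    def test_complete_separation_three_vs_three(self):
        res = rank_sum_test([10, 11, 12], [1, 2, 3], method="exact")
        assert res.value == 9.0  # maximal U for the first group
        assert res.p_value == pytest.approx(2 / 20)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_path_matches_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 6, size=int(rng.integers(2, 5))).astype(float)
        b = rng.integers(0, 6, size=int(rng.integers(2, 5))).astype(float)
        res = rank_sum_test(a, b, method="exact")
        assert res.p_value == pytest.approx(permutation_rank_sum_p(a, b))

    def test_exact_no_ties_matches_scipy(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=6)
        b = rng.normal(size=5)
        res = rank_sum_test(a, b, method="exact")
        ref = mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert res.value == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_power_rises_with_shift(self):
        rng = np.random.default_rng(4)
        rates = []
        for shift in (0.0, 1.0, 2.0):
            hits = 0
            for _ in range(100):
                a = rng.normal(shift, 1, 30)
                b = rng.normal(0, 1, 30)
                if rank_sum_test(a, b).p_value < 0.05:
                    hits += 1
            rates.append(hits / 100)
        assert rates[0] < 0.15
        assert rates[0] < rates[1] < rates[2]


class TestTables:
    def test_correlation_table_self_anchor_is_one(self, cohort_metrics):
        table = correlation_table(cohort_metrics)
        assert table.loc["network_size", "network_size_rho"] == 1.0
        assert table.loc["age_months", "age_months_rho"] == 1.0

    def test_adjusted_p_not_below_raw(self, cohort_metrics):
        table = correlation_table(cohort_metrics)
        raw = table["network_size_p"].to_numpy(dtype=float)
        adj = table["network_size_p_fdr"].to_numpy(dtype=float)
        ok = ~np.isnan(raw)
        assert np.all(adj[ok] >= raw[ok] - 1e-12)

    def test_all_missing_column_reported_missing(self):
        df = pd.DataFrame(
            {
                "network_size": [3.0, 7, 9, 12, 4, 8],
                "age_months": [6.0, 20, 30, 44, 12, 28],
                "density": [np.nan] * 6,
            }
        )
        table = correlation_table(df, variables=["network_size", "age_months", "density"])
        assert np.isnan(table.loc["density", "network_size_rho"])
        assert table.loc["density", "network_size_n"] == 0

    def test_summary_constant_column_sd_zero(self):
        df = pd.DataFrame({"network_size": [5.0, 5.0, 5.0], "density": [0.2, 0.4, np.nan]})
        table = summary_table(df, variables=["network_size", "density"])
        assert table.loc["network_size", "sd"] == 0.0
        assert table.loc["density", "n"] == 2

    def test_summary_hand_computed_mean(self):
        df = pd.DataFrame({"network_size": [3.0, 10.0, 14.0]})
        table = summary_table(df, variables=["network_size"])
        assert table.loc["network_size", "mean"] == pytest.approx(9.0)
        assert table.loc["network_size", "min"] == 3.0
        assert table.loc["network_size", "max"] == 14.0


def test_null_cohort_adjusted_significance_controlled():
    """On cohorts with no configured effects, BH-adjusted correlation tables
    should flag something in at most ~5% of replicates."""
    rng = np.random.default_rng(8)
    reps, flagged = 250, 0
    for _ in range(reps):
        df = pd.DataFrame(
            rng.normal(size=(50, 6)),
            columns=["network_size", "age_months", "m1", "m2", "m3", "m4"],
        )
        table = correlation_table(
            df, variables=["network_size", "age_months", "m1", "m2", "m3", "m4"]
        )
        adj = pd.concat([table["network_size_p_fdr"], table["age_months_p_fdr"]])
        if (adj.dropna() < 0.05).any():
            flagged += 1
    se = math.sqrt(0.05 * 0.95 / reps)
    assert flagged / reps <= 0.05 + 2 * se
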