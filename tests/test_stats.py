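"""Group inference: OLS contrasts, Mann-Whitney, FDR, composite scores,
extreme-participant flagging."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import normdev as nd
from normdev.exceptions import DataError, ParameterError, SingularityError


class TestAdjustedRegression:
    def test_orthogonal_design_matches_normal_equations(self):
        """With mutually orthogonal centered columns, the predictor beta is
        cov(outcome, predictor)/var(predictor), via an independent solve."""
        predictor = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        age = np.array([1.0, 1.0, -1.0, -1.0, 0.0, 0.0])
        sex = np.array([1.0, -1.0, -1.0, 1.0, 0.0, 0.0])
        rng = np.random.default_rng(4)
        outcome = 2.0 * predictor + 0.5 * age + rng.normal(size=6)
        res = nd.adjusted_regression(outcome, predictor, age, sex)
        beta_oracle = np.cov(outcome, predictor, ddof=1)[0, 1] / np.var(predictor, ddof=1)
        X = np.column_stack([np.ones(6), predictor, age, sex])
        beta_ne = np.linalg.solve(X.T @ X, X.T @ outcome)[1]
        assert res.beta == pytest.approx(beta_ne, abs=1e-10)
        assert res.beta == pytest.approx(beta_oracle, abs=1e-10)

    def test_type_one_error_near_nominal_under_null(self):
        rng = np.random.default_rng(7)
        n, reps = 100, 1000
        rejections = 0
        for _ in range(reps):
            group = np.repeat([0.0, 1.0], n // 2)
            age = rng.uniform(50, 80, n)
            sex = rng.integers(0, 2, n).astype(float)
            outcome = rng.normal(size=n)  # independent of everything
            res = nd.adjusted_regression(outcome, group, age, sex)
            rejections += res.p < 0.05
        assert 0.032 <= rejections / reps <= 0.068

    def test_recovers_injected_group_effect(self):
        rng = np.random.default_rng(8)
        n = 400
        group = np.repeat([1.0, 0.0], n // 2)
        age = rng.uniform(50, 80, n)
        sex = rng.integers(0, 2, n).astype(float)
        outcome = -4.0 * group + 0.1 * age + rng.normal(scale=3.0, size=n)
        res = nd.adjusted_regression(outcome, group, age, sex, predictor_name="grp")
        assert abs(res.beta - (-4.0)) < 2 * res.se

    def test_constant_predictor_rejected(self):
        with pytest.raises(DataError, match="constant"):
            nd.adjusted_regression(np.arange(10.0), np.ones(10), np.arange(10.0),
                                   np.zeros(10))

    def test_collinear_design_rejected(self):
        age = np.arange(10.0)
        with pytest.raises(SingularityError):
            nd.adjusted_regression(np.arange(10.0), age.copy(), age,
                                   np.r_[np.zeros(5), np.ones(5)])

    def test_group_contrast_direction_matches_reporting_convention(self):
        """First-listed group coded 1: if it has lower counts, beta < 0."""
        rng = np.random.default_rng(9)
        df = pd.DataFrame({
            "group": ["PD"] * 50 + ["DLB"] * 50,
            "count": np.r_[rng.normal(3.6, 2, 50), rng.normal(8.7, 3, 50)],
            "age": rng.uniform(55, 80, 100),
            "sex": rng.integers(0, 2, 100),
        })
        res = nd.group_contrast(df, "count", ("PD", "DLB"))
        assert res.beta < 0
        assert res.predictor == "PD_vs_DLB"


def _exact_mw_p(x, y):
    """Exhaustive-permutation two-sided p for the U statistic (oracle)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()

    def u_of(idx):
        r1 = ranks[list(idx)].sum()
        return r1 - n1 * (n1 + 1) / 2

    u_obs = u_of(range(n1))
    mean_u = n1 * len(y) / 2
    us = [u_of(c) for c in itertools.combinations(range(len(pooled)), n1)]
    dev = abs(u_obs - mean_u)
    return sum(abs(u - mean_u) >= dev - 1e-9 for u in us) / len(us)


class TestMannWhitney:
    def test_extreme_separation_small_samples(self):
        res = nd.mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert res.U == 0
        assert res.p == pytest.approx(1 / 3)
        assert res.method == "exact"

    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 5), (5, 5), (6, 6), (2, 6)])
    def test_exact_p_matches_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        res = nd.mann_whitney(x, y)
        assert res.method == "exact"
        assert res.p == pytest.approx(_exact_mw_p(x, y), abs=1e-12)
        assert 0 <= res.U <= n1 * n2

    def test_identical_samples_with_ties(self):
        x = np.array([1.0, 2.0, 2.0, 3.0] * 5)
        res = nd.mann_whitney(x, x)
        assert res.U == pytest.approx(len(x) ** 2 / 2)
        assert res.p > 0.99
        assert res.method == "asymptotic"

    def test_null_p_values_roughly_uniform(self):
        from scipy.stats import kstest
        rng = np.random.default_rng(11)
        ps = [nd.mann_whitney(rng.normal(size=40), rng.normal(size=40)).p
              for _ in range(1000)]
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_large_samples_use_asymptotic(self):
        rng = np.random.default_rng(12)
        res = nd.mann_whitney(rng.normal(size=120), rng.normal(size=120))
        assert res.method == "asymptotic"
        assert comb(240, 120) > 20_000

    def test_empty_group_rejected(self):
        with pytest.raises(DataError):
            nd.mann_whitney([], [1.0])


class TestFdr:
    def test_hand_step_up_toy_vector(self):
        # p=(0.01,0.02,0.03,0.04), m=4: q_(i) = min_j>=i p_(j)*4/j = 0.04 each
        np.testing.assert_allclose(nd.fdr_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert nd.fdr_adjust([0.123])[0] == pytest.approx(0.123)

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(nd.fdr_adjust(np.ones(7)), 1.0)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_step_up_properties(self, p):
        p = np.asarray(p)
        q = nd.fdr_adjust(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1 + 1e-12)
        # q preserves the order of p
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)
        # independent step-up computation
        m = len(p)
        sorted_p = p[order]
        q_sorted = np.minimum.accumulate((sorted_p * m / np.arange(1, m + 1))[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(q, oracle, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ParameterError):
            nd.fdr_adjust([0.5, 1.5])


class TestCompositeScore:
    means = pd.Series({"a": 10.0, "b": 20.0, "c": 30.0})
    sds = pd.Series({"a": 2.0, "b": 5.0, "c": 10.0})

    def test_at_control_means_is_zero(self):
        df = pd.DataFrame({"a": [10.0], "b": [20.0], "c": [30.0]})
        assert nd.composite_cognitive_score(df, self.means, self.sds)[0] == 0.0

    def test_symmetric_subtests_cancel(self):
        df = pd.DataFrame({"a": [12.0], "b": [15.0]})  # z = +1 and -1
        assert nd.composite_cognitive_score(df, self.means, self.sds)[0] == pytest.approx(0.0)

    def test_one_sd_above_on_all_subtests(self):
        df = pd.DataFrame({"a": [12.0], "b": [25.0], "c": [40.0]})
        assert nd.composite_cognitive_score(df, self.means, self.sds)[0] == pytest.approx(1.0)

    def test_missing_subtests_averaged_over_available(self):
        df = pd.DataFrame({"a": [12.0, np.nan], "b": [np.nan, np.nan]})
        out = nd.composite_cognitive_score(df, self.means, self.sds)
        assert out[0] == pytest.approx(1.0)
        assert np.isnan(out[1])  # all subtests missing -> flagged missing

    def test_zero_sd_rejected(self):
        with pytest.raises(ParameterError):
            nd.composite_cognitive_score(pd.DataFrame({"a": [1.0]}),
                                         pd.Series({"a": 0.0}), pd.Series({"a": 0.0}))


class TestExtremeFlagging:
    def test_isolated_high_count_flagged(self):
        # right-skewed counts spanning 0-24 (the shape total outlier counts
        # take in practice) plus one participant at 45: only 45 is extreme
        bulk = [0, 0, 0, 0, 1, 1, 1, 2, 2, 3, 3, 4, 5, 6, 8, 10, 14, 24]
        counts = pd.Series(bulk + [45], index=[f"p{i}" for i in range(19)])
        groups = pd.Series(["PD"] * 19, index=counts.index)
        assert nd.flag_extreme_participants(counts, groups) == ["p18"]

    def test_equal_counts_give_no_flags(self):
        counts = pd.Series([5.0] * 10, index=[f"p{i}" for i in range(10)])
        groups = pd.Series(["g"] * 10, index=counts.index)
        assert nd.flag_extreme_participants(counts, groups) == []

    def test_matches_brute_force_quartile_rule(self):
        rng = np.random.default_rng(13)
        counts = pd.Series(rng.poisson(5, 60).astype(float),
                           index=[f"p{i}" for i in range(60)])
        counts.iloc[::17] += 40
        groups = pd.Series(rng.choice(["a", "b"], 60), index=counts.index)
        flagged = set(nd.flag_extreme_participants(counts, groups))
        oracle = set()
        for g in ("a", "b"):
            vals = counts[groups == g]
            q1, q3 = np.percentile(vals, [25, 75])
            oracle |= set(vals.index[vals > q3 + 3 * (q3 - q1)])
        assert flagged == oracle
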