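"""Unit and property tests for the shared statistical kernels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from bftx.stats import (AdjustedPValues, CollinearityError,
                        InsufficientDataError, InvalidArgumentError,
                        UndefinedCorrelationError, bh_fdr,
                        bonferroni_threshold, interaction_model, levene_test,
                        ols_fit, pearson_r_test, t_tail_p,
                        two_sample_t_from_summary)


class TestTTailP:
    def test_zero_statistic_gives_one(self):
        assert t_tail_p(0.0, 30) == pytest.approx(1.0)

    def test_strictly_decreasing_in_abs_statistic(self):
        grid = np.linspace(0, 8, 50)
        p = [t_tail_p(t, 17) for t in grid]
        assert np.all(np.diff(p) < 0)

    def test_symmetry_two_sided(self):
        assert t_tail_p(2.3, 12) == pytest.approx(t_tail_p(-2.3, 12))

    def test_one_sided_is_half_two_sided_for_positive(self):
        assert t_tail_p(1.7, 40, two_sided=False) == pytest.approx(
            t_tail_p(1.7, 40) / 2)

    def test_normal_limit_at_large_df(self):
        assert t_tail_p(2.0, 10 ** 6) == pytest.approx(
            2 * sps.norm.sf(2.0), abs=1e-4)

    @pytest.mark.parametrize("stat,df", [(np.nan, 5), (np.inf, 5), (1.0, 0.5)])
    def test_invalid_arguments(self, stat, df):
        with pytest.raises(InvalidArgumentError):
            t_tail_p(stat, df)


class TestPearson:
    def test_identity_correlation(self, rng):
        x = rng.normal(size=20)
        res = pearson_r_test(x, 2 * x + 1)
        assert res.estimate == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_df_is_n_minus_2_after_listwise_deletion(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        y[3] = np.nan
        res = pearson_r_test(x, y)
        assert res.df == 12 and res.n_used == 14

    def test_agrees_with_permutation_oracle(self, rng):
        """Exact-test p matches a Monte-Carlo permutation p within 3 SE."""
        n_perm = 20_000
        for _ in range(5):
            n = int(rng.integers(12, 21))
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            res = pearson_r_test(x, y)
            xc = (x - x.mean()) / x.std()
            yc = (y - y.mean()) / y.std()
            perms = np.array([rng.permutation(yc) for _ in range(n_perm)])
            r_null = perms @ xc / n
            p_perm = (1 + np.sum(np.abs(r_null) >= abs(res.estimate))) / (n_perm + 1)
            # the t reference is the permutation law only asymptotically;
            # at n >= 12 the systematic gap is well under 0.005
            se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
            assert abs(res.p - p_perm) < 3 * se + 5e-3

    def test_constant_input_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r_test(np.ones(10), np.arange(10.0))

    def test_length_mismatch_raises(self):
        with pytest.raises(InvalidArgumentError):
            pearson_r_test(np.arange(5.0), np.arange(6.0))


class TestOLS:
    def test_exact_linear_fit_r2_one(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        y = 1.0 + 2 * X.a - 0.5 * X.b + 3 * X.c
        res = ols_fit(y, X)
        assert res.r_squared == pytest.approx(1.0)
        assert res.term("a").estimate == pytest.approx(2.0)

    def test_binary_predictor_equals_pooled_two_sample_t(self, rng):
        g = np.repeat([0.0, 1.0], [12, 18])
        y = rng.normal(size=30) + 0.8 * g
        res = ols_fit(y, pd.DataFrame({"g": g})).term("g")
        ref = two_sample_t_from_summary(
            y[g == 1].mean(), y[g == 1].std(ddof=1), 18,
            y[g == 0].mean(), y[g == 0].std(ddof=1), 12)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.p)

    def test_matches_normal_equations_oracle(self, rng):
        """Coefficients equal the brute-force (X'X)^-1 X'y solution."""
        for _ in range(20):
            X = pd.DataFrame(rng.normal(size=(20, 4)),
                             columns=list("abcd"))
            y = rng.normal(size=20)
            res = ols_fit(y, X)
            X1 = np.column_stack([np.ones(20), X.to_numpy()])
            beta = np.linalg.solve(X1.T @ X1, X1.T @ y)
            got = res.params.to_numpy()
            assert np.allclose(got, beta, rtol=1e-8)

    def test_collinearity_names_offending_column(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=25)})
        X["b"] = 2 * X.a
        with pytest.raises(CollinearityError) as exc:
            ols_fit(rng.normal(size=25), X)
        assert "b" in exc.value.columns

    def test_listwise_deletion_reports_used_n(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=30)})
        y = rng.normal(size=30)
        y[:4] = np.nan
        assert ols_fit(y, X).n_used == 26

    def test_too_few_rows_raises(self, rng):
        with pytest.raises(InsufficientDataError):
            ols_fit(rng.normal(size=3),
                    pd.DataFrame(rng.normal(size=(3, 3))))


class TestInteraction:
    def test_equal_slopes_no_noise_gives_zero_interaction(self):
        x = np.linspace(0, 1, 40)
        g = np.repeat([0.0, 1.0], 20)
        y = 2.0 + 0.7 * x + 0.3 * g
        res = interaction_model(y, x, g)
        assert res.estimate == pytest.approx(0.0, abs=1e-10)

    def test_power_with_noise_matched_to_effect(self):
        """Planted slopes -0.5 vs 0 at n=85, noise sd matched to the
        effect: the interaction is detected at p<0.05 in >=80% of reps."""
        rng = np.random.default_rng(2024)
        hits = 0
        reps = 300
        for _ in range(reps):
            g = np.repeat([0.0, 1.0], [29, 56])
            x = rng.normal(size=85)
            slope = np.where(g == 0, -0.5, 0.0)
            y = slope * x + rng.normal(0, 0.5, 85)
            res = interaction_model(y, x, g)
            hits += res.p < 0.05
        assert hits / reps >= 0.8


class TestLevene:
    def test_identical_groups_give_zero_statistic(self):
        v = np.concatenate([np.arange(10.0), np.arange(10.0)])
        g = np.repeat([0, 1], 10)
        assert levene_test(v, g).statistic == pytest.approx(0.0, abs=1e-12)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(7)
        rej = 0
        reps = 2000
        for _ in range(reps):
            v = rng.normal(size=60)
            g = np.repeat([0, 1], 30)
            rej += levene_test(v, g).p < 0.05
        assert 0.04 <= rej / reps <= 0.06

    def test_power_for_sd_ratio_two(self):
        rng = np.random.default_rng(8)
        rej = 0
        reps = 500
        for _ in range(reps):
            v = np.concatenate([rng.normal(0, 1, 40), rng.normal(0, 2, 40)])
            g = np.repeat([0, 1], 40)
            rej += levene_test(v, g).p < 0.05
        assert rej / reps > 0.8

    def test_mean_center_option(self, rng):
        v = rng.normal(size=40)
        g = np.repeat([0, 1], 20)
        assert levene_test(v, g, center="mean").statistic != pytest.approx(
            levene_test(v, g, center="median").statistic)

    def test_small_group_raises(self):
        with pytest.raises(InvalidArgumentError):
            levene_test([1.0, 2.0, 3.0], [0, 0, 1])


class TestBHFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]).q[0] == pytest.approx(0.2)

    def test_hand_computed_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04]).q
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_q_never_below_p_and_permutation_invariant(self, rng):
        p = rng.uniform(size=50)
        res = bh_fdr(p)
        assert np.all(res.q >= res.p_raw - 1e-15)
        perm = rng.permutation(50)
        res2 = bh_fdr(p[perm])
        assert np.allclose(res2.q, res.q[perm])

    def test_monotone_when_sorted(self, rng):
        p = np.sort(rng.uniform(size=40))
        assert np.all(np.diff(bh_fdr(p).q) >= -1e-15)

    def test_out_of_range_raises(self):
        with pytest.raises(InvalidArgumentError):
            bh_fdr([0.1, 1.2])

    def test_bonferroni_threshold(self):
        assert bonferroni_threshold(8) == pytest.approx(0.00625)
        with pytest.raises(InvalidArgumentError):
            bonferroni_threshold(0)


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=60))
def test_bh_fdr_properties_hold_for_arbitrary_p_vectors(p):
    """q in [p, 1] elementwise and monotone along the sorted order."""
    res = bh_fdr(p)
    assert np.all(res.q >= res.p_raw - 1e-15)
    assert np.all(res.q <= 1.0 + 1e-15)
    order = np.argsort(res.p_raw, kind="mergesort")
    assert np.all(np.diff(res.q[order]) >= -1e-12)


@settings(derandomize=True, max_examples=50)
@given(st.floats(min_value=-50, max_value=50),
       st.floats(min_value=-50, max_value=50),
       st.integers(min_value=1, max_value=500))
def test_t_tail_p_monotone_in_abs_statistic(a, b, df):
    lo, hi = sorted([abs(a), abs(b)])
    assert t_tail_p(hi, df) <= t_tail_p(lo, df) + 1e-15


def test_welch_vs_pooled_differ_under_unequal_n_and_var():
    pooled = two_sample_t_from_summary(1.0, 2.0, 50, 0.0, 0.5, 10)
    welch = two_sample_t_from_summary(1.0, 2.0, 50, 0.0, 0.5, 10, welch=True)
    assert pooled.statistic != pytest.approx(welch.statistic)
    assert welch.df < pooled.df
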