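"""Statistical-test contracts against closed-form and enumeration oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from mitopattern.stats import (
    InsufficientDataError,
    holm_adjust,
    kruskal_wallis,
    linear_regression,
    mann_whitney,
    one_way_anova,
    welch_t,
    welch_t_from_stats,
)


def _welch_closed_form(x, y):
    """Independent re-derivation of Welch's statistic and p-value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    v1, v2 = x.var(ddof=1) / n1, y.var(ddof=1) / n2
    t = (x.mean() - y.mean()) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return t, df, p


def _mw_enumeration_p(x, y):
    """Brute-force exact two-sided Mann-Whitney p over all group splits."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    offset = n1 * (n1 + 1) / 2
    u_obs = ranks[:n1].sum() - offset
    us = [
        ranks[list(c)].sum() - offset
        for c in itertools.combinations(range(len(pooled)), n1)
    ]
    us = np.array(us)
    eps = 1e-9
    p_ge = (us >= u_obs - eps).mean()
    p_le = (us <= u_obs + eps).mean()
    return min(1.0, 2 * min(p_ge, p_le))


class TestWelch:
    def test_identical_samples_null(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = welch_t(x, x)
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_reduces_to_student_under_equal_n_and_variance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 12)
        y = x + 0.5  # same sample variance, shifted
        res = welch_t(x, y)
        t_student, p_student = sps.ttest_ind(x, y, equal_var=True)
        assert res.statistic == pytest.approx(float(t_student), abs=1e-10)
        assert res.pvalue == pytest.approx(float(p_student), abs=1e-10)
        assert res.df == pytest.approx(len(x) + len(y) - 2, abs=1e-9)

    def test_matches_closed_form_oracle(self):
        x, y = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        res = welch_t(x, y)
        t, df, p = _welch_closed_form(x, y)
        assert res.statistic == pytest.approx(t, abs=1e-12)
        assert res.df == pytest.approx(df, abs=1e-12)
        assert res.pvalue == pytest.approx(p, abs=1e-12)

    def test_summary_stats_variant_agrees_with_samples(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(0, 1, 20), rng.normal(0.4, 2, 15)
        full = welch_t(x, y)
        summ = welch_t_from_stats(
            x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
        )
        assert summ.statistic == pytest.approx(full.statistic, abs=1e-10)
        assert summ.pvalue == pytest.approx(full.pvalue, abs=1e-10)

    def test_welch_df_bounds(self):
        rng = np.random.default_rng(21)
        x, y = rng.normal(0, 1, 8), rng.normal(0, 3, 15)
        res = welch_t(x, y)
        assert min(len(x), len(y)) - 1 <= res.df <= len(x) + len(y) - 2

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            welch_t([1.0], [2.0, 3.0])


class TestMannWhitney:
    def test_complete_separation_exact_p(self):
        # 2 of C(4,2)=6 assignments are as extreme: two-sided p = 2/6
        res = mann_whitney([1.0, 2.0], [10.0, 20.0])
        assert res.pvalue == pytest.approx(1.0 / 3.0)
        assert res.note == "exact enumeration"

    def test_identical_samples_with_ties(self):
        res = mann_whitney([1.0, 2.0], [1.0, 2.0])
        assert res.pvalue == pytest.approx(1.0)

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 6), (5, 5), (2, 9)])
    def test_exact_equals_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 100 + n2)
        for _ in range(5):
            x = rng.integers(0, 8, n1).astype(float)  # integers force ties
            y = rng.integers(0, 8, n2).astype(float)
            res = mann_whitney(x, y)
            assert res.pvalue == pytest.approx(_mw_enumeration_p(x, y), abs=1e-12)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(17)
        x = rng.normal(0, 1, 5)
        y = rng.normal(0.5, 1, 6)
        res = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert res.pvalue == pytest.approx(float(ref.pvalue), abs=1e-12)
        assert res.statistic == pytest.approx(float(ref.statistic), abs=1e-12)

    def test_large_sample_normal_branch(self):
        rng = np.random.default_rng(23)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.8, 1, 25)
        res = mann_whitney(x, y)
        assert res.note.startswith("normal approximation")
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.pvalue == pytest.approx(float(ref.pvalue), rel=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            mann_whitney([], [1.0])


class TestAnovaKruskal:
    def test_identical_constant_groups_null(self):
        res = one_way_anova([[2.0, 2.0, 2.0], [2.0, 2.0, 2.0]])
        assert res.pvalue == pytest.approx(1.0)

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(31)
        groups = [list(rng.normal(0, 1, 10)) for _ in range(3)]
        groups[1] = [g + 10.0 for g in groups[1]]
        res = one_way_anova(groups)
        assert res.pvalue < 1e-6

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(41)
        x, y = rng.normal(0, 1, 10), rng.normal(0.7, 1, 10)
        f = one_way_anova([x, y])
        t_student, _ = sps.ttest_ind(x, y, equal_var=True)
        assert f.statistic == pytest.approx(float(t_student) ** 2, abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            one_way_anova([[1.0, 2.0]])

    def test_kruskal_identical_pooled_data(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = kruskal_wallis([g, g, g])
        assert res.statistic == pytest.approx(0.0, abs=1e-10)

    def test_kruskal_matches_scipy(self):
        rng = np.random.default_rng(51)
        groups = [rng.normal(m, 1, 8) for m in (0, 0.5, 1.5)]
        res = kruskal_wallis(groups)
        ref_h, ref_p = sps.kruskal(*groups)
        assert res.statistic == pytest.approx(float(ref_h), abs=1e-10)
        assert res.pvalue == pytest.approx(float(ref_p), abs=1e-10)


class TestLinearRegression:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = linear_regression(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_three_point_normal_equations(self):
        x = np.array([0.0, 1.0, 3.0])
        y = np.array([1.0, 2.0, 2.0])
        fit = linear_regression(x, y)
        # hand-solved normal equations
        sx, sy, sxx, sxy, n = x.sum(), y.sum(), (x * x).sum(), (x * y).sum(), 3
        slope = (n * sxy - sx * sy) / (n * sxx - sx**2)
        intercept = (sy - slope * sx) / n
        assert fit.slope == pytest.approx(slope, abs=1e-12)
        assert fit.intercept == pytest.approx(intercept, abs=1e-12)

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(61)
        rejections = 0
        n_sims = 1000
        for _ in range(n_sims):
            x = rng.normal(0, 1, 50)
            y = rng.normal(0, 1, 50)  # independent of x
            rejections += linear_regression(x, y).pvalue < 0.05
        assert abs(rejections / n_sims - 0.05) <= 0.015

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            linear_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestProperties:
    from hypothesis import given, settings, strategies as st

    finite = st.floats(-1e6, 1e6, allow_nan=False)

    @given(
        x=st.lists(finite, min_size=3, max_size=8),
        y=st.lists(finite, min_size=3, max_size=8),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_welch_two_sided_is_twice_smaller_tail(self, x, y):
        try:
            two = welch_t(x, y).pvalue
            g = welch_t(x, y, sided="greater").pvalue
            l = welch_t(x, y, sided="less").pvalue
        except Exception:
            return  # degenerate draws are rejected upstream, nothing to check
        assert 0.0 <= two <= 1.0
        assert two == pytest.approx(min(1.0, 2 * min(g, l)), abs=1e-12)

    @given(
        x=st.lists(st.integers(0, 5), min_size=1, max_size=6),
        y=st.lists(st.integers(0, 5), min_size=1, max_size=6),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_mann_whitney_symmetric_in_group_order(self, x, y):
        x = [float(v) for v in x]
        y = [float(v) for v in y]
        assert mann_whitney(x, y).pvalue == pytest.approx(
            mann_whitney(y, x).pvalue, abs=1e-12
        )


class TestHolm:
    def test_monotone_and_bounded(self):
        p = np.array([0.01, 0.04, 0.03, 0.5])
        adj = holm_adjust(p)
        assert np.all(adj >= p) and np.all(adj <= 1.0)
        # order of adjusted values respects order of raw values
        assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-12)
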