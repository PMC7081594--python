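"""Regression on paired means, ANOVA, Tukey-Kramer HSD, Shapiro-Wilk.

The Tukey table is cross-checked against the statsmodels implementation and
against a brute-force evaluation of the studentized-range formula.
"""

import numpy as np
import pytest
import scipy.stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from mycometry import one_way_anova, paired_mean_regression, shapiro_wilk_report, tukey_hsd
from mycometry.errors import DegenerateDataError, InsufficientDataError
from mycometry.stats import pairwise_q


class TestPairedMeanRegression:
    def test_exact_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        fit = paired_mean_regression(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_hand_computed_oracle(self):
        # normal equations by hand for (1,1), (2,3), (3,2), (4,4):
        # Sxx = 5, Sxy = 4 -> slope 0.8, intercept 0.5, r^2 = (4/5)^2 = 0.64
        fit = paired_mean_regression([1, 2, 3, 4], [1, 3, 2, 4])
        assert fit.slope == pytest.approx(0.8)
        assert fit.intercept == pytest.approx(0.5)
        assert fit.r_squared == pytest.approx(0.64)

    def test_random_instances_match_normal_equations(self):
        from conftest import pooled_ols_oracle

        rng = np.random.default_rng(3)
        for _ in range(100):
            n = rng.integers(3, 12)
            x = rng.uniform(1, 10, n)
            y = rng.uniform(1, 10, n)
            slope, intercept = pooled_ols_oracle(x, y)
            fit = paired_mean_regression(x, y)
            assert fit.slope == pytest.approx(slope, rel=1e-10, abs=1e-10)
            assert fit.intercept == pytest.approx(intercept, rel=1e-10, abs=1e-10)

    def test_band_contains_fitted_line(self):
        rng = np.random.default_rng(8)
        x = np.arange(1.0, 9.0)
        y = 1.5 * x + rng.normal(0, 1, x.size)
        fit = paired_mean_regression(x, y)
        line = fit.predict(fit.band_x)
        assert np.all(fit.band_lower <= line + 1e-12)
        assert np.all(fit.band_upper >= line - 1e-12)

    def test_band_is_t_based_mean_response_interval(self):
        """Width at x-bar equals t_{n-2} * s / sqrt(n)."""
        rng = np.random.default_rng(9)
        x = np.linspace(1, 10, 8)
        y = 2 * x + rng.normal(0, 0.7, x.size)
        fit = paired_mean_regression(x, y, band_points=1001)
        resid = fit.y - fit.predict(fit.x)
        s = np.sqrt((resid**2).sum() / (fit.n - 2))
        half_at_mean = sps.t.ppf(0.975, fit.n - 2) * s / np.sqrt(fit.n)
        i = np.argmin(np.abs(fit.band_x - fit.x.mean()))
        measured = (fit.band_upper[i] - fit.band_lower[i]) / 2
        assert measured == pytest.approx(half_at_mean, rel=1e-3)

    def test_r_squared_affine_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 5, 6)
        y = rng.uniform(0, 5, 6)
        f1 = paired_mean_regression(x, y)
        f2 = paired_mean_regression(3 * x - 1, -2 * y + 7)
        assert f1.r_squared == pytest.approx(f2.r_squared, rel=1e-12)

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            paired_mean_regression([1, 2], [1, 2])
        with pytest.raises(DegenerateDataError):
            paired_mean_regression([2, 2, 2], [1, 2, 3])


class TestAnova:
    def test_two_groups_equals_squared_t(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 11)
        res = one_way_anova([a, b])
        t, p_t = sps.ttest_ind(a, b, equal_var=True)
        assert res.f_statistic == pytest.approx(t**2, rel=1e-10)
        assert res.p_value == pytest.approx(p_t, rel=1e-10)
        assert (res.df_between, res.df_within) == (1, 17)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(m, 1, n) for m, n in [(0, 5), (1, 7), (0.5, 6)]]
        res = one_way_anova(groups)
        f, p = sps.f_oneway(*groups)
        assert res.f_statistic == pytest.approx(f, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-12)

    def test_constant_groups_sentinel(self):
        res = one_way_anova([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]])
        assert res.degenerate
        assert np.isinf(res.f_statistic)
        assert res.p_value == 0.0

    def test_small_group_raises(self):
        with pytest.raises(InsufficientDataError):
            one_way_anova([[1.0, 2.0], [3.0]])


class TestTukey:
    def _groups(self, seed=0, k=4, n=6):
        rng = np.random.default_rng(seed)
        return [rng.normal(m, 1, n) for m in np.linspace(0, 2, k)]

    def test_identical_groups_never_reject(self):
        g = [1.0, 2.0, 3.0, 4.0]
        table = tukey_hsd([g, g, g])
        assert not table["reject"].any()
        assert np.allclose(table["q"], 0.0)

    def test_brute_force_formula_oracle(self):
        groups = self._groups(seed=7)
        table = tukey_hsd(groups)
        k = len(groups)
        n_tot = sum(len(g) for g in groups)
        msw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups) / (n_tot - k)
        row = 0
        for i in range(k):
            for j in range(i + 1, k):
                q = abs(np.mean(groups[j]) - np.mean(groups[i])) / np.sqrt(
                    (msw / 2) * (1 / len(groups[i]) + 1 / len(groups[j]))
                )
                assert table.loc[row, "q"] == pytest.approx(q, rel=1e-12)
                row += 1

    def test_matches_statsmodels(self):
        groups = self._groups(seed=13, k=3, n=5)
        table = tukey_hsd(groups)
        data = np.concatenate(groups)
        labels = np.repeat([f"group{i}" for i in range(3)], [len(g) for g in groups])
        sm_res = pairwise_tukeyhsd(data, labels, alpha=0.05)
        assert np.allclose(table["mean_diff"], sm_res.meandiffs, rtol=1e-10)
        assert np.allclose(table["p_adj"], sm_res.pvalues, atol=1e-6)
        assert np.array_equal(table["reject"], sm_res.reject)

    def test_two_groups_decision_equals_pooled_t(self):
        """q = t * sqrt(2): the HSD and pooled-t decisions coincide at k=2."""
        rng = np.random.default_rng(21)
        agree = 0
        for _ in range(200):
            a = rng.normal(0, 1, rng.integers(3, 9))
            b = rng.normal(rng.uniform(0, 1.5), 1, rng.integers(3, 9))
            reject_hsd = tukey_hsd([a, b])["reject"].item()
            _, p_t = sps.ttest_ind(a, b, equal_var=True)
            agree += reject_hsd == (p_t < 0.05)
        assert agree == 200

    def test_degenerate_variance_raises(self):
        with pytest.raises(DegenerateDataError):
            tukey_hsd([[1.0, 1.0], [2.0, 2.0]])

    def test_critical_value_decision_matches_p_value_decision(self):
        groups = self._groups(seed=3)
        table = tukey_hsd(groups, alpha=0.05)
        qs, _, df = pairwise_q(groups)
        q_crit = sps.studentized_range.ppf(0.95, len(groups), df)
        assert np.array_equal(table["reject"].to_numpy(), qs > q_crit)


class TestShapiro:
    def test_matches_scipy(self):
        rng = np.random.default_rng(2)
        v = rng.normal(0, 1, 40)
        w, p = shapiro_wilk_report(v)
        w2, p2 = sps.shapiro(v)
        assert (w, p) == (pytest.approx(w2), pytest.approx(p2))

    def test_skewed_samples_are_rejected_often(self):
        rng = np.random.default_rng(6)
        rejections = sum(
            shapiro_wilk_report(np.exp(rng.normal(0, 1.5, 100)))[1] < 0.05
            for _ in range(50)
        )
        assert rejections >= 45

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            shapiro_wilk_report([1.0, 2.0])
        with pytest.raises(DegenerateDataError):
            shapiro_wilk_report([3.0] * 10)
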