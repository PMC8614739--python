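import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2

from ratemc.eiv_regression import (
    confidence_band,
    error_ellipse,
    mc_regression,
    ols_fit,
    york_fit,
    york_objective,
)


def grid_search_slope(x, sx, y, sy, b_center, half_width=0.05, step=1e-4):
    """Brute-force minimiser of the both-axes objective over a slope grid.

    For each candidate slope the intercept follows analytically from the
    weighted normal equation; entirely independent of the iterative fit.
    """
    wx = np.where(sx > 0, 1.0 / np.maximum(sx, 1e-300) ** 2, 1e12)
    wy = np.where(sy > 0, 1.0 / np.maximum(sy, 1e-300) ** 2, 1e12)
    best = (np.inf, None, None)
    for b in np.arange(b_center - half_width, b_center + half_width + step / 2, step):
        w = wx * wy / (b * b * wy + wx)
        a = np.sum(w * (y - b * x)) / np.sum(w)
        s = york_objective(x, sx, y, sy, a, b)
        if s < best[0]:
            best = (s, b, a)
    return best


class TestOLS:
    def test_perfect_line(self):
        f = ols_fit([0, 1, 2], [0, 1, 2])
        assert f.intercept == pytest.approx(0.0, abs=1e-12)
        assert f.slope == pytest.approx(1.0)

    def test_two_points_interpolate_exactly(self):
        f = ols_fit([1.0, 3.0], [2.0, 8.0])
        assert f.slope == pytest.approx(3.0)
        assert f.intercept == pytest.approx(-1.0)

    def test_recovers_known_slope_within_three_se(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0, 1, 20)
        y = 0.13 * x + rng.normal(0, 0.001, 20)
        f = ols_fit(x, y)
        assert abs(f.slope - 0.13) < 3 * f.se_slope

    def test_identical_x_rejected(self):
        with pytest.raises(ValueError):
            ols_fit([1.0, 1.0], [0.0, 1.0])


class TestYork:
    def test_two_points_fit_exactly_for_any_weights(self):
        f = york_fit([0.0, 2.0], [0.5, 0.1], [1.0, 5.0], [0.2, 0.3])
        assert f.predict(0.0) == pytest.approx(1.0, abs=1e-9)
        assert f.predict(2.0) == pytest.approx(5.0, abs=1e-9)

    def test_exact_x_limit_equals_ols(self):
        rng = np.random.default_rng(1)
        x = np.linspace(0, 2, 12)
        y = 1.0 + 0.5 * x + rng.normal(0, 0.05, 12)
        yk = york_fit(x, np.zeros(12), y, np.full(12, 0.05))
        ls = ols_fit(x, y)
        assert yk.slope == pytest.approx(ls.slope, abs=1e-6)
        assert yk.intercept == pytest.approx(ls.intercept, abs=1e-6)

    def test_matches_grid_search_oracle_on_varying_weights(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, 10)
        sx = rng.uniform(0.05, 0.8, 10)
        sy = rng.uniform(0.05, 0.8, 10)
        y = 1.5 + 0.7 * x + rng.normal(0, sy)
        xo = x + rng.normal(0, sx)
        f = york_fit(xo, sx, y, sy)
        s_grid, b_grid, _ = grid_search_slope(xo, sx, y, sy, f.slope)
        assert abs(f.slope - b_grid) < 1e-4
        s_fit = york_objective(xo, sx, y, sy, f.intercept, f.slope)
        assert s_fit <= s_grid + 1e-9

    def test_objective_at_solution_beats_ols_line(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 5, 8)
        sx = rng.uniform(0.1, 0.4, 8)
        sy = rng.uniform(0.1, 0.4, 8)
        y = -0.5 + 2.0 * x + rng.normal(0, sy)
        f = york_fit(x, sx, y, sy)
        ls = ols_fit(x, y)
        assert york_objective(x, sx, y, sy, f.intercept, f.slope) <= york_objective(
            x, sx, y, sy, ls.intercept, ls.slope
        )

    def test_axis_swap_maps_slope_to_reciprocal(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(1, 10, 9)
        sx = rng.uniform(0.1, 0.3, 9)
        sy = rng.uniform(0.1, 0.3, 9)
        y = 0.3 + 1.7 * x + rng.normal(0, sy)
        f = york_fit(x, sx, y, sy)
        g = york_fit(y, sy, x, sx)
        assert g.slope == pytest.approx(1.0 / f.slope, abs=1e-8)

    def test_all_exact_coordinates_rejected(self):
        with pytest.raises(ValueError, match="nonzero uncertainty"):
            york_fit([0, 1, 2], np.zeros(3), [0, 1, 2], np.zeros(3))

    def test_degenerate_vertical_geometry_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            york_fit([1.0, 1.0, 1.0], [0.1] * 3, [0, 1, 2], [0.1] * 3)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_property_fit_minimises_objective(self, seed):
        # randomized <=12-point instances: the iterative solution never loses
        # to the brute-force slope grid on the printed objective
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        x = rng.uniform(-5, 5, n)
        if np.ptp(x) < 0.5:
            x[0] += 1.0
        sx = rng.uniform(0.02, 0.5, n)
        sy = rng.uniform(0.02, 0.5, n)
        b_true = rng.uniform(-3, 3)
        y = rng.uniform(-2, 2) + b_true * x + rng.normal(0, sy)
        xo = x + rng.normal(0, sx)
        f = york_fit(xo, sx, y, sy)
        s_grid, b_grid, _ = grid_search_slope(
            xo, sx, y, sy, f.slope, half_width=0.01, step=1e-4
        )
        assert york_objective(xo, sx, y, sy, f.intercept, f.slope) <= s_grid + 1e-9
        assert abs(f.slope - b_grid) <= 1e-4


class TestMCRegression:
    def test_zero_sigma_collapses_the_cloud(self):
        x = np.linspace(0, 1, 6)
        y = 2.0 * x + 1.0
        res = mc_regression(x, 0.0, y, 0.0, fitter="ols", n=50, seed=0)
        assert np.all(res.cov_P == 0.0)
        np.testing.assert_allclose(res.param_cloud[:, 1], 2.0, atol=1e-12)

    def test_york_mc_sigma_agrees_with_analytic_se(self):
        # on well-conditioned data the York analytic errors and the Monte
        # Carlo cloud spread tell the same story (within 25% at N=500)
        rng = np.random.default_rng(5)
        x = np.linspace(0.1, 0.4, 8)
        sx = np.full(8, 0.02)
        sy = np.full(8, 0.003)
        y = -0.004 + 0.157 * x + rng.normal(0, sy)
        f = york_fit(x, sx, y, sy)
        mc = mc_regression(x, sx, y, sy, fitter="york", n=500, seed=6)
        assert mc.sigma_P[0] == pytest.approx(f.se_intercept, rel=0.25)
        assert mc.sigma_P[1] == pytest.approx(f.se_slope, rel=0.25)

    def test_leverage_point_inflates_ols_but_not_york(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([np.linspace(0.1, 0.3, 7), [0.6]])
        sx = np.concatenate([np.full(7, 0.01), [0.15]])
        sy = np.full(8, 0.002)
        y = -0.004 + 0.157 * x + rng.normal(0, sy)
        mo = mc_regression(x, sx, y, sy, fitter="ols", n=500, seed=8)
        my = mc_regression(x, sx, y, sy, fitter="york", n=500, seed=8)
        assert mo.sigma_P[0] / my.sigma_P[0] > 2.0

    def test_fixed_seed_is_bit_reproducible(self):
        x = np.linspace(0, 1, 6)
        y = 2.0 * x
        a = mc_regression(x, 0.05, y, 0.05, fitter="york", n=100, seed=9)
        b = mc_regression(x, 0.05, y, 0.05, fitter="york", n=100, seed=9)
        np.testing.assert_array_equal(a.param_cloud, b.param_cloud)

    def test_n_below_ten_rejected(self):
        with pytest.raises(ValueError):
            mc_regression([0, 1], 0.1, [0, 1], 0.1, n=5)


class TestBandsAndEllipse:
    def test_zero_noise_band_has_zero_width(self):
        x = np.linspace(0, 1, 5)
        y = 2 * x - 1
        fit = ols_fit(x, y)
        mc = mc_regression(x, 0.0, y, 0.0, fitter="ols", n=50, seed=0)
        lo, hi = confidence_band(mc, fit, x, k_sigma=1.0)
        np.testing.assert_allclose(lo, hi, atol=1e-12)
        np.testing.assert_allclose(lo, y, atol=1e-10)

    def test_band_width_monotone_in_k(self):
        rng = np.random.default_rng(10)
        x = np.linspace(0, 1, 8)
        y = x + rng.normal(0, 0.1, 8)
        fit = ols_fit(x, y)
        mc = mc_regression(x, 0.05, y, 0.1, fitter="ols", n=200, seed=11)
        lo1, hi1 = confidence_band(mc, fit, x, 1.0)
        lo3, hi3 = confidence_band(mc, fit, x, 3.0)
        assert np.all(hi3 - lo3 > hi1 - lo1)

    def test_one_sigma_band_coverage_near_683(self):
        # quick version of the calibration study: pointwise coverage of the
        # true line by the 1-sigma band over 60 replications
        rng = np.random.default_rng(12)
        x = np.linspace(0.1, 0.4, 8)
        sx = np.full(8, 0.02)
        sy = np.full(8, 0.003)
        a0, b0 = -0.004, 0.157
        xg = np.linspace(0.1, 0.4, 9)
        hits = []
        for _ in range(60):
            xo = x + rng.normal(0, sx)
            yo = a0 + b0 * x + rng.normal(0, sy)
            f = york_fit(xo, sx, yo, sy)
            mc = mc_regression(
                xo, sx, yo, sy, fitter="york", n=200,
                seed=int(rng.integers(2**31)), x_grid=xg,
            )
            lo, hi = confidence_band(mc, f, xg, 1.0)
            truth = a0 + b0 * xg
            hits.append(((truth >= lo) & (truth <= hi)).mean())
        assert np.mean(hits) == pytest.approx(0.683, abs=0.08)

    def test_equal_variances_give_a_circle(self):
        semi, rot, _ = error_ellipse(np.eye(2) * 4.0, coverage=0.683)
        assert semi[0] == pytest.approx(semi[1])

    def test_coverage_683_scale_factor(self):
        semi, _, _ = error_ellipse(np.eye(2), coverage=0.683)
        # chi-square(2) quantile: -2 ln(1 - 0.683) = 2.295...
        assert semi[0] ** 2 == pytest.approx(-2.0 * np.log(1 - 0.683))
        assert semi[0] ** 2 == pytest.approx(chi2.ppf(0.683, 2))

    def test_cloud_fraction_inside_683_ellipse(self):
        rng = np.random.default_rng(13)
        cov = np.array([[2.0, 0.8], [0.8, 1.0]])
        cloud = rng.multivariate_normal([0, 0], cov, size=4000)
        semi, rot, _ = error_ellipse(cov, coverage=0.683)
        R = np.array([[np.cos(rot), np.sin(rot)], [-np.sin(rot), np.cos(rot)]])
        z = cloud @ R.T / semi
        frac = np.mean(np.sum(z**2, axis=1) <= 1.0)
        assert frac == pytest.approx(0.683, abs=0.05)

    def test_non_psd_covariance_rejected(self):
        with pytest.raises(ValueError):
            error_ellipse(np.array([[1.0, 2.0], [2.0, 1.0]]))
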