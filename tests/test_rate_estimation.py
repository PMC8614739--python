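import numpy as np
import pytest

from conftest import max_relative_error, recover_rates
from ratemc._ivp import KIND_BIOMASS, KIND_STANDARD, KIND_STRICT, integrate_balance
from ratemc.data_model import Profile
from ratemc.rate_estimation import (
    BalanceKind,
    BalanceSpec,
    fit_interval_rate,
    mu_from_series,
    q_from_series,
)

BIOMASS = BalanceSpec("biomass", BalanceKind.BIOMASS_GROWTH)


class TestFitIntervalRate:
    def test_exponential_growth_recovers_mu(self):
        # cX: 1 -> e over 1 h without dilution is exactly mu = 1
        mu = fit_interval_rate(BIOMASS, 1.0, np.e, None, None, None, 0.0, 1.0)
        assert mu == pytest.approx(1.0, abs=1e-7)

    def test_steady_state_growth_equals_dilution(self):
        mu = fit_interval_rate(BIOMASS, 10.0, 10.0, None, 0.1, None, 0.0, 1.0)
        assert mu == pytest.approx(0.1, abs=1e-9)

    def test_substrate_steady_state_matches_closed_form(self):
        # cS constant at 1 g/L, cS,feed = 500 g/L, FS = 0.002 L/h, V = 2 L,
        # cX = 10 g/L: the balance closes at qS = -(c_feed - cS) FS / (V cX)
        spec = BalanceSpec("substrate", BalanceKind.UPTAKE, strict_dilution=False)
        feed_term = 500.0 * 0.002 / 2.0
        D = 0.002 / 2.0
        q = fit_interval_rate(spec, 1.0, 1.0, 10.0, D, feed_term, 0.0, 1.0)
        assert q == pytest.approx(-(500.0 - 1.0) * 0.002 / (2.0 * 10.0), abs=1e-6)

    def test_substrate_steady_state_euler_oracle(self):
        spec = BalanceSpec("substrate", BalanceKind.UPTAKE, strict_dilution=False)
        q = fit_interval_rate(spec, 1.0, 1.0, 10.0, 0.001, 0.5, 0.0, 1.0)
        # brute-force forward Euler at 1e-5 h steps with the fitted rate
        h = 1e-5
        c = 1.0
        for _ in range(int(1 / h)):
            c += h * (q * 10.0 + 0.5 - 0.001 * c)
        assert c == pytest.approx(1.0, abs=1e-5)

    def test_strict_dilution_variant_changes_the_sink_term(self):
        strict = BalanceSpec("substrate", BalanceKind.UPTAKE, strict_dilution=True)
        q = fit_interval_rate(strict, 1.0, 1.0, 10.0, 0.001, 0.5, 0.0, 1.0)
        # steady state: 0 = q cX + feed - D cX
        assert q == pytest.approx(-(0.5 - 0.001 * 10.0) / 10.0, abs=1e-6)

    def test_product_linear_accumulation(self):
        spec = BalanceSpec("product", BalanceKind.PRODUCTION)
        q = fit_interval_rate(spec, 0.0, 0.1, 10.0, None, None, 0.0, 2.0)
        assert q == pytest.approx(0.005, abs=1e-9)

    def test_no_change_no_sources_gives_zero_rate(self):
        spec = BalanceSpec("product", BalanceKind.PRODUCTION)
        q = fit_interval_rate(spec, 1.0, 1.0, 10.0, None, None, 0.0, 2.0)
        assert q == pytest.approx(0.0, abs=1e-9)

    def test_finite_difference_limit(self):
        # no feed, no dilution, constant biomass: q -> dc / (dt cX)
        spec = BalanceSpec("product", BalanceKind.PRODUCTION)
        q = fit_interval_rate(spec, 2.0, 2.6, 12.0, None, None, 0.0, 1.5)
        assert q == pytest.approx(0.6 / (1.5 * 12.0), abs=1e-6)

    def test_interior_points_enter_the_objective(self):
        # consistent 3-point exponential data: grouped fit returns the same mu
        t = np.array([0.0, 1.0, 2.0])
        c = np.exp(0.3 * t)
        mu = fit_interval_rate(
            BIOMASS, c[0], c[2], None, None, None, 0.0, 2.0,
            interior=[(1.0, c[1])],
        )
        assert mu == pytest.approx(0.3, abs=1e-6)

    def test_rejects_empty_interval(self):
        with pytest.raises(ValueError):
            fit_interval_rate(BIOMASS, 1.0, 1.0, None, None, None, 1.0, 1.0)


class TestSeriesEstimation:
    def test_grouped_intervals_cover_the_horizon(self):
        t = np.arange(0.0, 6.1, 1.0)
        c = np.exp(0.2 * t)
        rates, _ = mu_from_series(t, c, group=2)
        assert rates.interval_starts[0] == 0.0
        assert rates.interval_ends[-1] == 6.0
        np.testing.assert_allclose(rates.values, 0.2, atol=1e-6)

    def test_mass_balance_closure_on_every_interval(self, ecoli_noisy):
        # the fitted rate must reproduce the measured end point when the
        # interval ODE is re-integrated (the balance closes by construction)
        scn, truth, ds = ecoli_noisy
        cx = ds.series("biomass")
        D = Profile(truth.times, truth.dilution)
        rates, _ = mu_from_series(cx.times, cx.values, D=D)
        tg = truth.times
        dg = truth.dilution
        zeros = np.zeros_like(tg)
        for i in range(len(rates)):
            t0, t1 = rates.interval_starts[i], rates.interval_ends[i]
            c_end = integrate_balance(
                cx.values[i], t0, t1, rates.values[i], KIND_BIOMASS,
                tg, zeros, dg, zeros, 1e-10, 1e-14,
            )
            assert c_end == pytest.approx(cx.values[i + 1], rel=1e-6)


class TestDatasetLevelAPI:
    def test_estimate_mu_and_q_from_a_dataset(self):
        from ratemc.data_model import MeasurementSeries, ProcessDataset
        from ratemc.rate_estimation import estimate_mu, estimate_q

        t = np.array([0.0, 1.0, 2.0])
        ds = ProcessDataset(
            organism_label="toy",
            initial_volume=1.0,
            offline=[
                MeasurementSeries("biomass", t, np.exp(0.2 * t)),
                MeasurementSeries("product", t, 0.05 * t),
            ],
        )
        mu, cx_prof = estimate_mu(ds)
        np.testing.assert_allclose(mu.values, 0.2, atol=1e-6)
        qp = estimate_q(ds, "product", cX_profile=cx_prof, kind="production")
        # dc/dt = q cX with cX = e^{0.2t}: q ~ 0.05 dt / int(cX)
        expect = 0.05 / (np.diff(np.exp(0.2 * t) / 0.2))
        np.testing.assert_allclose(qp.values, expect, rtol=1e-5)


class TestRoundTripRecovery:
    def test_noise_free_rates_recovered(self, ecoli_clean, cho_clean):
        # aligned piecewise-constant truth is recovered to <= 1e-5 relative
        for scn, truth in (ecoli_clean, cho_clean):
            est = recover_rates(scn, truth)
            for name, r in est.items():
                key = "mu" if name == "mu" else name
                assert max_relative_error(r.values, scn.rates[key]) < 1e-5, name

    def test_quasi_steady_state_mu_equals_mean_dilution(self):
        # equal biomass endpoints under constant dilution force mu = D
        D = Profile([0.0, 2.0], [0.05, 0.05])
        rates, _ = mu_from_series(np.array([0.0, 2.0]), np.array([4.0, 4.0]), D=D)
        assert rates.values[0] == pytest.approx(0.05, abs=1e-8)

    def test_integrator_agrees_with_scipy(self):
        # independent check of the custom RK45 against solve_ivp on a stiff-free
        # balance with time-varying coefficients
        from scipy.integrate import solve_ivp

        tg = np.linspace(0.0, 2.0, 41)
        xg = 8.0 * np.exp(0.1 * tg)
        dg = 0.006 + 0.001 * np.sin(tg)
        fg = 0.5 + 0.1 * tg
        q = -0.25
        mine = integrate_balance(3.0, 0.0, 2.0, q, KIND_STRICT, tg, xg, dg, fg, 1e-10, 1e-14)

        def rhs(t, c):
            x = np.interp(t, tg, xg)
            return q * x + np.interp(t, tg, fg) - np.interp(t, tg, dg) * x

        # integrate knot-to-knot so solve_ivp's error control never has to
        # step across a kink of the interpolated coefficients
        c = 3.0
        for a, b in zip(tg[:-1], tg[1:]):
            c = solve_ivp(rhs, (a, b), [c], rtol=1e-11, atol=1e-12).y[0, -1]
        assert mine == pytest.approx(c, rel=1e-8)

    def test_standard_form_integrator_agrees_with_scipy(self):
        from scipy.integrate import solve_ivp

        tg = np.linspace(0.0, 2.0, 41)
        xg = np.full_like(tg, 50.0)
        dg = np.full_like(tg, 0.002)
        fg = np.full_like(tg, 0.1)
        q = -0.001
        mine = integrate_balance(1.5, 0.0, 2.0, q, KIND_STANDARD, tg, xg, dg, fg, 1e-10, 1e-14)
        ref = solve_ivp(
            lambda t, c: q * 50.0 + 0.1 - 0.002 * c, (0.0, 2.0), [1.5],
            rtol=1e-11, atol=1e-12,
        ).y[0, -1]
        assert mine == pytest.approx(ref, rel=1e-8)

    def test_uptake_sign_convention_is_negative(self, ecoli_clean):
        scn, truth = ecoli_clean
        est = recover_rates(scn, truth)
        assert np.all(est["glycerol"].values < 0)
        assert np.all(est["product"].values > 0)
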