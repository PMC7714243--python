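"""AR model identification, fitting, roots and residual diagnostics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import gaitar as g
from gaitar import ar


class TestDemean:
    def test_example(self):
        centered, mean = ar.demean([1.0, 1.2, 1.1])
        assert mean == pytest.approx(1.1)
        assert centered == pytest.approx([-0.1, 0.1, 0.0])
        assert abs(centered.mean()) < 1e-12

    def test_reconstruction_and_idempotence(self):
        rng = np.random.default_rng(5)
        x = rng.normal(3.0, 1.0, 500)
        centered, mean = ar.demean(x)
        assert np.allclose(centered + mean, x)
        again, mean2 = ar.demean(centered)
        assert np.allclose(again, centered) and abs(mean2) < 1e-12

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ar.demean([1.0, 2.0])


class TestAcf:
    def test_lag_zero_is_one(self, ar2_sample):
        assert ar.acf(ar2_sample, 5)[0] == 1.0

    def test_alternating_series_closed_form(self):
        n = 100
        x = np.tile([1.0, -1.0], n // 2)
        # direct summation: r1 = -(n-1)/n for a centered alternating series
        assert ar.acf(x, 1)[1] == pytest.approx(-(n - 1) / n, abs=1e-12)

    def test_ar2_lag1_matches_yule_walker(self, ar2_sample):
        # rho1 = phi1 / (1 - phi2) = 0.625 for (0.5, 0.2)
        assert ar.acf(ar2_sample, 1)[1] == pytest.approx(0.625, abs=0.01)

    def test_matches_statsmodels_biased_estimator(self):
        from statsmodels.tsa.stattools import acf as sm_acf

        rng = np.random.default_rng(17)
        x = rng.normal(size=400).cumsum()
        assert ar.acf(x, 20) == pytest.approx(sm_acf(x, nlags=20, fft=False), abs=1e-10)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            ar.acf(np.ones(50), 5)


class TestPacf:
    def test_lag1_equals_acf_lag1(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=300)
        assert ar.pacf(x, 5)[0] == pytest.approx(ar.acf(x, 5)[1], abs=1e-12)

    def test_ar2_pacf_cuts_off_after_lag_two(self, ar2_sample):
        p = ar.pacf(ar2_sample, 20)
        assert p[1] == pytest.approx(0.2, abs=0.01)  # pacf(2) = phi2 for AR(2)
        bound = 1.96 / np.sqrt(ar2_sample.size)
        frac_inside = np.mean(np.abs(p[2:]) < bound)
        assert frac_inside >= 0.9

    def test_matches_statsmodels_durbin_levinson(self):
        from statsmodels.tsa.stattools import pacf as sm_pacf

        rng = np.random.default_rng(23)
        x = rng.normal(size=500) + 0.5 * np.sin(np.arange(500) / 7.0)
        assert ar.pacf(x, 15) == pytest.approx(sm_pacf(x, nlags=15, method="ldb")[1:],
                                               abs=1e-8)


class TestFitAr:
    def test_white_noise_coefficients_near_zero(self):
        x = g.simulate_ar2_series(0.0, 0.0, 100_000, 1.0, seed=9)
        fit = ar.fit_ar(x, order=2)
        assert abs(fit.phi1) < 0.02 and abs(fit.phi2) < 0.02

    def test_parameter_recovery_long_series(self, ar2_sample):
        fit = ar.fit_ar(ar2_sample, order=2)
        assert fit.phi1 == pytest.approx(0.5, abs=0.01)
        assert fit.phi2 == pytest.approx(0.2, abs=0.01)
        assert fit.sigma2 == pytest.approx(1.0, rel=0.02)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ar.fit_ar(np.arange(5.0), order=2)

    def test_matches_statsmodels_autoreg(self):
        from statsmodels.tsa.ar_model import AutoReg

        x = g.simulate_ar2_series(0.4, -0.3, 2_000, 0.5, mean=1.1, seed=31)
        fit = ar.fit_ar(x, order=2)
        centered, _ = ar.demean(x)
        ref = AutoReg(centered, lags=2, trend="n").fit()
        assert fit.coeffs == pytest.approx(ref.params, abs=1e-8)

    def test_yule_walker_option_close_to_cls(self, ar2_sample):
        cls_fit = ar.fit_ar(ar2_sample, method="cls")
        yw_fit = ar.fit_ar(ar2_sample, method="yule_walker")
        assert yw_fit.coeffs == pytest.approx(cls_fit.coeffs, abs=0.01)

    def test_one_step_reconstruction(self):
        x = g.simulate_ar2_series(0.6, -0.2, 300, 0.3, mean=2.0, seed=8)
        fit = ar.fit_ar(x, order=2)
        centered, _ = ar.demean(x)
        assert np.allclose(fit.fitted + fit.resid, centered[2:])
        assert fit.resid.size == fit.n - fit.order
        assert abs(fit.resid.mean()) < 3 * np.sqrt(fit.sigma2 / fit.n)

    def test_delta_reported_from_mean(self):
        x = g.simulate_ar2_series(0.5, 0.2, 5_000, 0.2, mean=1.1, seed=12)
        fit = ar.fit_ar(x)
        assert fit.delta == pytest.approx(fit.mean * (1 - fit.phi1 - fit.phi2))


class TestCharacteristicRoots:
    @pytest.mark.parametrize(
        "phi1, phi2, expected",
        [
            (0.0, 0.0, [0.0, 0.0]),
            (1.5, -0.56, [0.8, 0.7]),
        ],
    )
    def test_real_examples(self, phi1, phi2, expected):
        roots = ar.characteristic_roots(phi1, phi2)
        assert np.allclose(sorted(roots.real, reverse=True), expected, atol=1e-9)
        assert np.allclose(roots.imag, 0.0)

    def test_complex_pair_modulus(self):
        roots = ar.characteristic_roots(0.0, -0.5)
        assert np.allclose(np.abs(roots), np.sqrt(0.5))
        assert roots[0].conjugate() == roots[1]

    @given(st.floats(-2.5, 2.5), st.floats(-1.5, 1.5))
    def test_roots_satisfy_characteristic_equation(self, phi1, phi2):
        for m in ar.characteristic_roots(phi1, phi2):
            assert abs(m * m - phi1 * m - phi2) < 1e-10

    @given(st.floats(-2.5, 2.5), st.floats(-1.5, 1.5))
    def test_coefficient_duality(self, phi1, phi2):
        m1, m2 = ar.characteristic_roots(phi1, phi2)
        assert abs((m1 + m2).real - phi1) < 1e-9
        assert abs((-m1 * m2).real - phi2) < 1e-9

    def test_matches_numpy_roots(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            p1, p2 = rng.uniform(-2.5, 2.5), rng.uniform(-1.5, 1.5)
            mine = sorted(ar.characteristic_roots(p1, p2), key=lambda z: (z.real, z.imag))
            ref = sorted(np.roots([1.0, -p1, -p2]).astype(complex),
                         key=lambda z: (z.real, z.imag))
            assert np.allclose(mine, ref, atol=1e-9)


class TestStationarityRootEquivalence:
    def test_triangle_membership_iff_roots_in_unit_disc(self):
        from gaitar import triangle as tri

        rng = np.random.default_rng(4)
        for _ in range(2_000):
            p1, p2 = rng.uniform(-2.5, 2.5), rng.uniform(-1.5, 1.5)
            member = tri.is_stationary(p1, p2)
            if member.boundary:
                continue
            max_mod = np.max(np.abs(ar.characteristic_roots(p1, p2)))
            assert member.inside == (max_mod < 1.0)


class TestResidualDiagnostics:
    def test_matches_scipy_statistic(self):
        import warnings

        from scipy import stats as sps

        rng = np.random.default_rng(0)
        x = rng.normal(size=250)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = sps.anderson(x, "norm").statistic
        assert ar.anderson_darling_normality(x).statistic == pytest.approx(ref, abs=1e-10)

    def test_normal_sample_not_rejected(self):
        x = np.random.default_rng(101).normal(size=5_000)
        assert not ar.anderson_darling_normality(x).reject

    def test_exponential_sample_rejected(self):
        x = np.random.default_rng(102).exponential(size=5_000)
        assert ar.anderson_darling_normality(x).reject

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ar.anderson_darling_normality(np.ones(50))
        with pytest.raises(ValueError):
            ar.anderson_darling_normality(np.arange(5.0))

    def test_fit_residuals_of_gaussian_ar2_look_normal(self, ar2_sample):
        fit = ar.fit_ar(ar2_sample[:5_000])
        diag = ar.residual_diagnostics(fit)
        assert not diag.reject
        assert diag.hist_counts.sum() == fit.resid.size


class TestSelectOrder:
    def test_recovers_known_orders(self):
        x2 = g.simulate_ar2_series(0.5, 0.2, 100_000, 1.0, seed=61)
        assert ar.select_order(x2, 20).order == 2
        x1 = g.simulate_ar2_series(0.6, 0.0, 100_000, 1.0, seed=62)
        assert ar.select_order(x1, 20).order == 1
        white = g.simulate_ar2_series(0.0, 0.0, 100_000, 1.0, seed=63)
        assert ar.select_order(white, 20).order == 0

    def test_max_order_bound(self):
        with pytest.raises(ValueError):
            ar.select_order(np.random.default_rng(1).normal(size=40), 10)
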