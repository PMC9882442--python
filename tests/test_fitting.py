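"""Curve fitting: Rice expectation, the four estimators, map-level driver."""

import numpy as np
import pytest
from scipy.integrate import quad

from t2relax.fitting import (
    FIT_METHODS,
    FitBounds,
    fit_image_series,
    fit_loglin,
    fit_nlls,
    fit_nlls_bound,
    fit_nlls_rice,
    rician_expected_magnitude,
)
from t2relax.series import ImageSeries
from t2relax.signal_model import decay_signal, rician_corrupt
from t2relax.synthetic import generate_truth_maps, synthesize_sample


def rice_mean_quadrature(nu, sigma):
    """Independent oracle: numerically integrate the Rice density."""

    def integrand(m):
        z = m * nu / sigma**2
        if z < 700:
            log_bessel = np.log(np.i0(z))
        else:
            # asymptotic I0(z) ~ e^z/sqrt(2 pi z) * (1 + 1/8z + 9/128z^2)
            log_bessel = z - 0.5 * np.log(2 * np.pi * z) + np.log1p(
                1 / (8 * z) + 9 / (128 * z**2)
            )
        log_pdf = np.log(m / sigma**2) - (m**2 + nu**2) / (2 * sigma**2) + log_bessel
        return m * np.exp(log_pdf)

    val, _ = quad(integrand, 0, nu + 12 * sigma, limit=200)
    return val


class TestRicianExpectedMagnitude:
    def test_rayleigh_limit(self):
        assert rician_expected_magnitude(0.0, 1.0) == pytest.approx(
            np.sqrt(np.pi / 2), rel=1e-12
        )

    @pytest.mark.parametrize("nu,sigma", [(1.0, 1.0), (10.0, 0.1), (0.3, 0.08)])
    def test_matches_quadrature(self, nu, sigma):
        assert rician_expected_magnitude(nu, sigma) == pytest.approx(
            rice_mean_quadrature(nu, sigma), rel=1e-9
        )

    def test_high_snr_asymptote(self):
        assert rician_expected_magnitude(10.0, 0.1) == pytest.approx(
            np.sqrt(10.0**2 + 0.1**2), rel=1e-6
        )

    def test_exceeds_noiseless_value(self, rng):
        nu = rng.uniform(0, 5, 100)
        sigma = rng.uniform(1e-3, 1, 100)
        assert np.all(rician_expected_magnitude(nu, sigma) > nu)

    def test_monte_carlo_consistency(self):
        nu, sigma, n = 0.5, 0.2, 10**6
        draws = rician_corrupt(np.full(n, nu), sigma, np.random.default_rng(0))
        se = draws.std() / np.sqrt(n)
        assert draws.mean() == pytest.approx(
            rician_expected_magnitude(nu, sigma), abs=3 * se
        )

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            rician_expected_magnitude(1.0, 0.0)


class TestFitLoglin:
    def test_exact_on_noiseless(self, grid):
        res = fit_loglin(decay_signal(0.8, 0.5, grid), grid)
        assert res.s0 == pytest.approx(0.8, abs=1e-9)
        assert res.rate == pytest.approx(2.0, abs=1e-9)
        assert res.t == pytest.approx(0.5, abs=1e-9)

    def test_series_with_zero_sample_is_finite(self, grid):
        y = decay_signal(0.5, 0.3, grid)
        y[-1] = 0.0
        res = fit_loglin(y, grid)
        assert np.isfinite(res.s0) and np.isfinite(res.rate)
        assert res.converged

    def test_all_nonpositive_flagged(self, grid):
        res = fit_loglin(np.zeros(grid.n), grid)
        assert not res.converged
        assert res.rate == FitBounds().rate_interval[1]

    def test_property_sweep_noiseless(self, grid, rng):
        worst = 0.0
        for _ in range(100):
            s0, t = rng.uniform(0.05, 1), rng.uniform(0.045, 4)
            res = fit_loglin(decay_signal(s0, t, grid), grid)
            worst = max(worst, abs(res.t - t))
        assert worst < 1e-6


class TestIterativeFits:
    def test_noiseless_recovery(self, grid):
        y = decay_signal(0.6, 1.7, grid)
        init = fit_loglin(y, grid)
        for fn in (fit_nlls, fit_nlls_bound):
            res = fn(y, grid, init)
            assert res.t == pytest.approx(1.7, abs=1e-8)
            assert res.converged

    def test_rice_noiseless_sigma_at_floor(self, grid):
        y = decay_signal(0.6, 1.7, grid)
        res = fit_nlls_rice(y, grid, fit_loglin(y, grid))
        assert res.t == pytest.approx(1.7, abs=1e-6)
        # sigma collapses to (within optimizer tolerance of) its floor
        assert res.sigma_rice < 5 * FitBounds().sigma_interval[0]

    def test_bound_contract_on_pure_noise(self, grid, rng):
        bounds = FitBounds()
        for _ in range(20):
            y = rician_corrupt(np.zeros(grid.n), 0.1, rng)
            res = fit_nlls_bound(y, grid, fit_loglin(y, grid), bounds)
            assert bounds.rate_interval[0] <= res.rate <= bounds.rate_interval[1]
            assert bounds.s0_interval[0] <= res.s0 <= bounds.s0_interval[1]

    def test_positive_t_bias_at_low_snr_and_rice_reduction(self, grid):
        # Gaussian-loss NLLS overestimates T on Rician data; the Rice-mean
        # model reduces the magnitude of that bias.
        n = 800
        clean = np.tile(decay_signal(0.3, 1.0, grid), (n, 1))
        noisy = rician_corrupt(clean, 0.1, np.random.default_rng(42))
        t_nlls, t_rice = [], []
        for row in noisy:
            init = fit_loglin(row, grid)
            t_nlls.append(fit_nlls(row, grid, init).t)
            t_rice.append(fit_nlls_rice(row, grid, init).t)
        bias_nlls = np.median(t_nlls) - 1.0
        bias_rice = np.median(t_rice) - 1.0
        assert bias_nlls > 0
        assert abs(bias_rice) < abs(bias_nlls)

    def test_high_snr_accuracy(self, grid):
        n = 200
        clean = np.tile(decay_signal(0.5, 1.0, grid), (n, 1))
        noisy = rician_corrupt(clean, 0.001, np.random.default_rng(3))
        errs = [abs(fit_nlls(r, grid, fit_loglin(r, grid)).t - 1.0) for r in noisy]
        assert np.median(errs) < 0.01

    def test_bounded_no_worse_than_unbounded(self, grid):
        # accuracy comparison, paired on the same noisy draws
        n = 400
        clean = np.tile(decay_signal(0.3, 1.0, grid), (n, 1))
        noisy = rician_corrupt(clean, 0.08, np.random.default_rng(11))
        e_nlls, e_bound = [], []
        for row in noisy:
            init = fit_loglin(row, grid)
            e_nlls.append(abs(fit_nlls(row, grid, init).t - 1.0))
            e_bound.append(abs(fit_nlls_bound(row, grid, init).t - 1.0))
        assert np.median(e_bound) <= np.median(e_nlls)

    def test_fixed_sigma_rice_mode(self, grid):
        y = rician_corrupt(
            decay_signal(0.4, 0.8, grid), 0.05, np.random.default_rng(5)
        )
        res = fit_nlls_rice(y, grid, fit_loglin(y, grid), sigma_fixed=0.05)
        assert res.sigma_rice is None
        assert res.converged


class TestFitImageSeries:
    def test_noiseless_map_recovery_all_methods(self, grid, rng):
        truth = generate_truth_maps("urand", (8, 8), rng)
        sample = synthesize_sample(truth, grid, rng, sigma_range=(0.0, 0.0))
        for method in FIT_METHODS:
            pmap = fit_image_series(sample.series, method=method)
            assert np.max(np.abs(pmap.t - truth.t_map)) < 1e-4, method

    def test_loglin_large_map_finite_and_deterministic(self, grid, rng):
        truth = generate_truth_maps("urand", (128, 128), rng)
        sample = synthesize_sample(truth, grid, rng)
        a = fit_image_series(sample.series, method="loglin")
        b = fit_image_series(sample.series, method="loglin")
        assert np.all(np.isfinite(a.t)) and np.all(np.isfinite(a.s0))
        np.testing.assert_array_equal(a.t, b.t)

    def test_unknown_method_rejected(self, grid, rng):
        truth = generate_truth_maps("urand", (8, 8), rng)
        sample = synthesize_sample(truth, grid, rng)
        with pytest.raises(ValueError, match="loglin"):
            fit_image_series(sample.series, method="bogus")

    def test_dead_pixels_masked_not_fatal(self, grid):
        data = np.zeros((4, 4, grid.n))
        data[0, 0] = decay_signal(0.5, 1.0, grid)
        series = ImageSeries(data=data, grid=grid)
        pmap = fit_image_series(series, method="nlls_bound")
        assert pmap.t[0, 0] == pytest.approx(1.0, abs=1e-6)
        assert pmap.converged is not None
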