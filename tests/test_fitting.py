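"""Noise estimation, Rician likelihood and voxel-wise ML fitting."""

import math
import warnings

import numpy as np
import pytest
from scipy.special import i0

from mcdmri import compartments as cpt
from mcdmri import fitting as fit
from mcdmri.compartments import ParamVector, get_model, predict_scheme
from mcdmri.fitting import (
    NoiseEstimate,
    estimate_noise_sigma,
    expected_rician_mean,
    fit_voxel,
    rician_loglik,
)

from conftest import make_noisy


class TestNoiseEstimate:
    def test_rayleigh_sampling_oracle(self):
        """1e5 Rayleigh(sigma=1) background samples recover sigma to 1%."""
        rng = np.random.default_rng(0)
        samples = np.hypot(rng.standard_normal(100_000), rng.standard_normal(100_000))
        est = estimate_noise_sigma(samples)
        assert 0.99 <= est.sigma <= 1.01

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        x = np.hypot(rng.standard_normal(500), rng.standard_normal(500))
        s1 = estimate_noise_sigma(x).sigma
        s2 = estimate_noise_sigma(3.7 * x).sigma
        assert s2 == pytest.approx(3.7 * s1, rel=1e-12)

    def test_minimum_sample_count(self):
        with pytest.raises(ValueError):
            estimate_noise_sigma(np.ones(10))

    def test_all_zero_background_rejected(self):
        with pytest.raises(ValueError):
            estimate_noise_sigma(np.zeros(100))

    def test_nex_scaling(self, full_scheme):
        est = NoiseEstimate(0.02)
        per = est.per_measurement(full_scheme)
        assert per[full_scheme.n_avg == 1][0] == pytest.approx(0.02)
        idx = np.where(full_scheme.n_avg == 4)[0]
        assert per[idx[0]] == pytest.approx(0.01)


class TestRicianLoglik:
    def test_single_point_reference_value(self):
        # x = A = sigma = 1: lnL = -1 + ln I0(1), frozen via scipy.special.i0
        expected = -1.0 + math.log(i0(1.0))
        assert rician_loglik([1.0], [1.0], 1.0) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(-0.7640856, abs=1e-6)

    def test_zero_amplitude_is_rayleigh_density(self):
        x, sigma = 0.7, 0.5
        expected = math.log(x / sigma**2) - x**2 / (2 * sigma**2)
        assert rician_loglik([x], [0.0], sigma) == pytest.approx(expected, rel=1e-12)

    def test_high_snr_approaches_gaussian(self):
        """At sigma = 1e-3 A with x = A the Rician and Gaussian
        log-densities agree closely per point."""
        A = 1.0
        sigma = 1e-3
        lnL = rician_loglik([A], [A], sigma)
        gauss = -0.5 * math.log(2 * math.pi * sigma**2)
        assert lnL == pytest.approx(gauss, abs=1e-3)

    def test_large_argument_stability(self):
        # exponentially scaled Bessel keeps the likelihood finite at SNR 1e4
        val = rician_loglik([1.0], [1.0], 1e-4)
        assert np.isfinite(val)

    def test_nonpositive_observations_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="non-positive"):
            v = rician_loglik([1.0, -0.1], [1.0, 1.0], 1.0)
        assert v == pytest.approx(rician_loglik([1.0], [1.0], 1.0))


class TestExpectedRicianMean:
    def test_zero_amplitude_rayleigh_mean(self):
        assert expected_rician_mean(0.0, 2.0) == pytest.approx(
            2.0 * math.sqrt(math.pi / 2), rel=1e-12
        )

    def test_high_snr_asymptote(self):
        sigma = 1.0
        A = 20.0
        assert expected_rician_mean(A, sigma) == pytest.approx(A, rel=0.002)

    def test_monotone_in_amplitude(self):
        sigma = 1.0
        vals = expected_rician_mean(np.linspace(0, 5, 50), sigma)
        assert np.all(np.diff(vals) > 0)

    def test_matches_sampling(self):
        rng = np.random.default_rng(2)
        A, sigma = 1.5, 0.8
        draws = np.hypot(A + sigma * rng.standard_normal(200_000),
                         sigma * rng.standard_normal(200_000))
        assert expected_rician_mean(A, sigma) == pytest.approx(
            draws.mean(), rel=0.01
        )


class TestFitVoxel:
    def test_noiseless_ball_recovered_exactly(self, full_scheme, full_cache):
        spec = get_model("Ball")
        x_true = np.array([0.8, 1.0, 0.08])
        data = predict_scheme(spec, x_true, full_cache)
        fr = fit_voxel(data, full_scheme, spec, NoiseEstimate(1e-6),
                       n_starts=1, seed=0, cache=full_cache)
        assert fr.params.D1 == pytest.approx(0.8, rel=1e-6)
        assert fr.params.T2 == pytest.approx(0.08, rel=1e-4)

    def test_reproducible_given_seed(self, full_scheme, full_cache,
                                     zs_clean_signal):
        data = make_noisy(zs_clean_signal, 50, seed=9,
                          n_avg=full_cache.n_avg)
        noise = NoiseEstimate(1 / 50)
        a = fit_voxel(data, full_scheme, "Zeppelin-Sphere", noise,
                      n_starts=3, seed=5, cache=full_cache)
        b = fit_voxel(data, full_scheme, "Zeppelin-Sphere", noise,
                      n_starts=3, seed=5, cache=full_cache)
        assert np.array_equal(a.x, b.x)
        assert a.lnL == b.lnL

    def test_nested_model_likelihood_ordering(self, full_scheme, full_cache,
                                              zs_clean_signal):
        """Best-found lnL of a super-model is never materially below its
        sub-model's on the same data."""
        data = make_noisy(zs_clean_signal, 50, seed=11, n_avg=full_cache.n_avg)
        noise = NoiseEstimate(1 / 50)
        pairs = [("Ball", "Zeppelin"), ("Zeppelin", "Tensor"),
                 ("Ball-Sphere", "Zeppelin-Sphere")]
        lnL = {}
        for name in {n for p in pairs for n in p}:
            lnL[name] = fit_voxel(data, full_scheme, name, noise,
                                  n_starts=4, seed=3, cache=full_cache).lnL
        for sub, sup in pairs:
            assert lnL[sup] >= lnL[sub] - 1e-6

    def test_parameter_recovery_zeppelin_sphere_snr50(
        self, full_scheme, full_cache, zs_clean_signal, zs_truth
    ):
        """Median recovery over noise draws: f_I within 0.05, R within
        1 um (scaled-down replicate count for the routine suite)."""
        noise = NoiseEstimate(1 / 50)
        err_f, err_R = [], []
        for rep in range(8):
            data = make_noisy(zs_clean_signal, 50, seed=100 + rep,
                              n_avg=full_cache.n_avg)
            fr = fit_voxel(data, full_scheme, "Zeppelin-Sphere", noise,
                           n_starts=5, seed=rep, cache=full_cache)
            err_f.append(fr.params.f_I - zs_truth.f_I)
            err_R.append(fr.params.R - zs_truth.R)
        assert abs(np.median(err_f)) <= 0.05
        assert abs(np.median(err_R)) <= 1.0

    def test_unrestricted_truth_drives_R_to_upper_bound(
        self, full_scheme, full_cache
    ):
        """Data generated with fast free intracellular diffusion drive
        the fitted sphere radius to its 20-um ceiling (a 20-um sphere is
        the closest available surrogate for unrestricted diffusion)."""
        zb = get_model("Zeppelin-Ball")
        x = ParamVector(D1=0.8, D2=0.3, theta=0.9, phi=0.4, D_I=2.5,
                        f_I=0.4, S0=1.0, T2=0.08).to_array(zb)
        clean = predict_scheme(zb, x, full_cache)
        Rs = []
        for seed in range(20, 24):
            data = make_noisy(clean, 100, seed=seed, n_avg=full_cache.n_avg)
            fr = fit_voxel(data, full_scheme, "Zeppelin-Sphere",
                           NoiseEstimate(1 / 100), n_starts=6, seed=4,
                           cache=full_cache)
            Rs.append(fr.params.R)
        assert np.median(Rs) >= 19.0
        assert min(Rs) >= 15.0

    def test_data_length_mismatch(self, full_scheme):
        with pytest.raises(ValueError, match="length"):
            fit_voxel(np.ones(5), full_scheme, "Ball", NoiseEstimate(0.01))


def test_gaussian_regime_matches_least_squares(full_scheme, full_cache):
    """At SNR > 100 the Rician ML Ball fit agrees with plain nonlinear
    least squares within 1%."""
    from scipy.optimize import curve_fit

    spec = get_model("Ball")
    x_true = np.array([0.9, 1.0, 0.07])
    clean = predict_scheme(spec, x_true, full_cache)
    data = make_noisy(clean, 300, seed=33, n_avg=full_cache.n_avg)
    fr = fit_voxel(data, full_scheme, spec, NoiseEstimate(1 / 300),
                   n_starts=3, seed=0, cache=full_cache)

    b = full_cache.b_mm * 1e-3
    te = full_cache.TE_si

    def model(_, D, S0, T2):
        return S0 * np.exp(-te / T2) * np.exp(-b * D)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, _ = curve_fit(model, None, data, p0=[1.0, 1.0, 0.1],
                            bounds=([0.01, 0.1, 0.001], [3.0, 10.0, 3.0]))
    assert fr.params.D1 == pytest.approx(popt[0], rel=0.01)
    assert fr.params.S0 == pytest.approx(popt[1], rel=0.01)
    assert fr.params.T2 == pytest.approx(popt[2], rel=0.01)
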