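"""TIC linearization, mLDRW forward model, fitting, and derived features."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mpuscad.cudi_temporal import (
    TICVolume,
    compress_intensity,
    derive_temporal_features,
    fit_mldrw,
    fit_mldrw_volume,
    linearize_intensity,
    mldrw_curve,
)

T = np.arange(0.0, 120.0, 1.0)


def _tic(kappa=2.0, mu=20.0, t0=5.0, auc=100.0, t=T):
    return mldrw_curve(t, kappa, mu, t0, auc)


class TestLinearization:
    def test_round_trip(self, rng):
        raw = rng.uniform(0.0, 60.0, (3, 3, 3, 25))
        vol = linearize_intensity(raw, np.arange(25.0), dynamic_range_db=60.0)
        assert np.allclose(compress_intensity(vol.data), raw, atol=1e-10)

    def test_zero_db_maps_to_unity_and_monotone(self):
        raw = np.zeros((1, 1, 1, 25))
        raw[..., 10] = 30.0
        vol = linearize_intensity(raw, np.arange(25.0))
        assert vol.data[0, 0, 0, 0] == 1.0
        a, b = np.array([[[[10.0] * 25]]]), np.array([[[[20.0] * 25]]])
        va = linearize_intensity(a, np.arange(25.0)).data
        vb = linearize_intensity(b, np.arange(25.0)).data
        assert np.all(va < vb)

    def test_non_finite_masked(self):
        raw = np.full((2, 1, 1, 25), 5.0)
        raw[0, 0, 0, 3] = np.nan
        vol = linearize_intensity(raw, np.arange(25.0))
        assert not vol.mask[0, 0, 0] and vol.mask[1, 0, 0]


class TestMldrwCurve:
    def test_zero_before_appearance(self):
        t = np.linspace(0, 5.0, 50)
        assert np.all(mldrw_curve(t, 2.0, 20.0, 5.0, 1.0) == 0.0)

    def test_integral_equals_auc(self):
        # quadrature oracle: the curve is a normalized transit-time density
        t = np.linspace(0, 600, 600001)
        for kappa, mu, auc in [(2.0, 20.0, 37.0), (0.5, 40.0, 100.0), (5.0, 10.0, 3.0)]:
            integral = np.trapezoid(mldrw_curve(t, kappa, mu, 5.0, auc), t)
            assert abs(integral - auc) / auc < 0.01

    def test_peak_near_t0_plus_mu_for_large_kappa_mu(self):
        # asymptotic: peak time -> t0 + mu when kappa*mu >> 1 (here = 100)
        t = np.linspace(0, 60, 120001)
        c = mldrw_curve(t, 5.0, 20.0, 5.0, 1.0)
        assert abs(t[np.argmax(c)] - 25.0) < 0.15

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            mldrw_curve(T, -1.0, 20.0, 5.0, 1.0)
        with pytest.raises(ValueError):
            mldrw_curve(T, 2.0, 0.0, 5.0, 1.0)


class TestFitMldrw:
    def test_noiseless_recovery(self):
        fit = fit_mldrw(_tic(), T)
        assert fit.converged and fit.r2 > 0.999
        for got, want in zip(fit.as_array(), (2.0, 20.0, 5.0, 100.0)):
            assert abs(got - want) / want < 0.01

    def test_refit_fixed_point(self):
        fit = fit_mldrw(_tic(), T)
        refit = fit_mldrw(mldrw_curve(T, *fit.as_array()), T)
        assert np.allclose(refit.as_array(), fit.as_array(), rtol=1e-4)

    def test_all_zero_tic_not_converged(self):
        fit = fit_mldrw(np.zeros_like(T), T)
        assert not fit.converged and np.isnan(fit.kappa)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_mldrw(np.ones(10), np.arange(10.0))

    def test_noise_monte_carlo_kappa_efficiency(self, rng):
        # 100 voxels at 5% peak noise; the achievable precision is set by the
        # Cramer-Rao bound at these conditions, computed here as the oracle
        y0 = _tic()
        sigma = 0.05 * y0.max()
        p0 = np.array([2.0, 20.0, 5.0, 100.0])
        J = np.zeros((T.size, 4))
        for i in range(4):
            dp = p0.copy()
            h = 1e-5 * p0[i]
            dp[i] += h
            J[:, i] = (mldrw_curve(T, *dp) - y0) / h
        crlb_sd = np.sqrt(np.diag(np.linalg.inv(J.T @ J / sigma**2)))
        crlb_median = 0.674 * crlb_sd[0] / p0[0]  # half-normal median
        errs = []
        for _ in range(100):
            fit = fit_mldrw(y0 + sigma * rng.standard_normal(T.size), T)
            if fit.converged:
                errs.append(abs(fit.kappa - 2.0) / 2.0)
        assert np.median(errs) < 1.3 * crlb_median

    @given(st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_scale_equivariance(self, c):
        base = fit_mldrw(_tic(), T)
        scaled = fit_mldrw(c * _tic(), T)
        assert abs(scaled.auc - c * base.auc) / (c * base.auc) < 1e-3
        for name in ("kappa", "mu", "t0"):
            assert abs(getattr(scaled, name) - getattr(base, name)) < 1e-3 * abs(
                getattr(base, name)
            ) + 1e-6


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(7)
    n = 1000
    ks = rng.uniform(0.5, 2.5, n)
    ms = rng.uniform(12, 40, n)
    t0s = rng.uniform(5, 14, n)
    aus = rng.uniform(80, 220, n)
    Y = mldrw_curve(T, ks[:, None], ms[:, None], t0s[:, None], aus[:, None])[:, 0, :]
    vol = TICVolume(Y.reshape(10, 10, 10, -1), T)
    return fit_mldrw_volume(vol), {"kappa": ks, "mu": ms, "t0": t0s, "auc": aus}


class TestFitMldrwVolume:
    def test_zero_noise_closure(self, fitted):
        out, truth = fitted
        assert out["converged"].all()
        for name, true in truth.items():
            rel = np.abs(out[name].ravel() - true) / np.abs(true)
            assert np.mean(rel < 0.01) >= 0.99

    def test_agrees_with_scipy_path(self, fitted):
        # dual route: the batched LM against scipy.optimize.least_squares
        out, truth = fitted
        y = mldrw_curve(T, 1.3, 22.0, 8.0, 150.0)
        single = fit_mldrw(y, T)
        vol = TICVolume(y.reshape(1, 1, 1, -1), T)
        batched = fit_mldrw_volume(vol)
        for name in ("kappa", "mu", "t0", "auc"):
            s = getattr(single, name)
            b = batched[name][0, 0, 0]
            assert abs(s - b) / max(abs(s), 1e-9) < 1e-3

    def test_noise_bias_on_kappa(self):
        # fixed-seed Monte-Carlo: estimator bias < 5% at 5% noise, n = 500
        rng = np.random.default_rng(3)
        n = 500
        y0 = _tic()
        Y = y0[None, :] + 0.05 * y0.max() * rng.standard_normal((n, T.size))
        vol = TICVolume(np.clip(Y, 0, None).reshape(5, 10, 10, -1), T)
        out = fit_mldrw_volume(vol)
        k = out["kappa"][out["converged"]]
        assert abs(np.mean(k) - 2.0) / 2.0 < 0.05


@pytest.fixture(scope="module")
def feats():
    rng = np.random.default_rng(5)
    n = 64
    ks = rng.uniform(0.5, 2.5, n)
    ms = rng.uniform(12, 40, n)
    Y = mldrw_curve(T, ks[:, None], ms[:, None], 6.0, 100.0)[:, 0, :]
    vol = TICVolume(Y.reshape(4, 4, 4, -1), T)
    fits = fit_mldrw_volume(vol)
    return derive_temporal_features(fits, T), fits


class TestDerivedFeatures:
    def test_wash_in_positive(self, feats):
        f, fits = feats
        conv = fits["converged"]
        assert np.all(f["wash_in_time"][conv] > 0)

    def test_peak_matches_dense_evaluation(self, feats):
        # oracle: dense evaluation of the fitted curve on a fine global grid
        f, fits = feats
        i = (2, 2, 2)
        tg = np.linspace(fits["t0"][i], fits["t0"][i] + 3 * fits["mu"][i], 20001)
        dense = mldrw_curve(tg, fits["kappa"][i], fits["mu"][i], fits["t0"][i],
                            fits["auc"][i]).max()
        assert abs(f["peak_intensity"][i] - dense) / dense < 1e-3

    def test_all_missing_propagates(self):
        shape = (2, 2, 2)
        fits = {k: np.full(shape, np.nan) for k in ("kappa", "mu", "t0", "auc", "r2")}
        fits["converged"] = np.zeros(shape, dtype=bool)
        f = derive_temporal_features(fits, T)
        for v in f.values():
            assert np.isnan(v).all()
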