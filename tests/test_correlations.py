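"""Covariance estimation, multiexponential fits, spectral densities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zenospin.correlations import (CovarianceModel, complete_eed_coefficients,
                                   default_tau_grid, effective_correlation_time,
                                   empirical_covariance, estimate_covariance,
                                   fit_multiexponential, spectral_density)
from zenospin.observables import EED_LABELS, CouplingSeries
from zenospin.oracles import ou_realization


def _series(components: dict, dt: float = 0.1) -> CouplingSeries:
    n = len(next(iter(components.values())))
    return CouplingSeries(times=np.arange(n) * dt, components=components)


class TestEmpiricalCovariance:
    def test_white_noise(self, rng):
        v = 2.5
        xs = [np.sqrt(v) * rng.standard_normal(20_000) for _ in range(8)]
        lags, g = empirical_covariance(((x, x) for x in xs), dt=1.0, max_lag=20.0)
        assert g[0] == pytest.approx(v, rel=0.05)
        assert np.abs(g[1:]).max() < 0.05 * v

    def test_ou_closed_form(self, rng):
        v, tau, dt = 1.8, 5.0, 0.25
        xs = [np.sqrt(1.0) * ou_realization(np.array([v]), np.array([tau]),
                                            dt, 60_000, rng)
              for _ in range(12)]
        lags, g = empirical_covariance(((x, x) for x in xs), dt=dt,
                                       max_lag=3.0 * tau)
        expected = v * np.exp(-lags / tau)
        assert np.abs(g - expected).max() < 0.1 * v

    def test_cross_equals_auto_for_identical_series(self, rng):
        x = rng.standard_normal(5000)
        _, g_auto = empirical_covariance([(x, x)], dt=1.0, max_lag=10.0)
        _, g_cross = empirical_covariance([(x, x.copy())], dt=1.0, max_lag=10.0)
        assert np.array_equal(g_auto, g_cross)

    def test_mismatched_grids_rejected(self, rng):
        with pytest.raises(ValueError):
            empirical_covariance([(np.zeros(10), np.zeros(11))], 1.0, 2.0)

    def test_estimate_covariance_wrapper(self, rng):
        x = rng.standard_normal(4000)
        y = rng.standard_normal(4000)
        cs = _series({"a": x, "b": y})
        lags, g = estimate_covariance([cs], ("a", "a"), max_lag=5.0)
        _, g2 = empirical_covariance([(x, x)], dt=0.1, max_lag=5.0)
        assert np.allclose(g, g2)


class TestMultiexponentialFit:
    def test_recovers_basis_member(self):
        tau_grid = default_tau_grid()
        lags = np.arange(0, 2000.0, 0.5)
        m = 7
        g = 3.0 * np.exp(-lags / tau_grid[m])
        coeffs, resid = fit_multiexponential(lags, g, tau_grid)
        assert coeffs[m] == pytest.approx(3.0, abs=0.01)
        # small ridge keeps the recovery near-exact, not exact
        assert resid < 1e-4 * np.linalg.norm(g)

    def test_recovers_two_members(self):
        tau_grid = default_tau_grid()
        lags = np.arange(0, 2000.0, 0.5)
        g = 2.0 * np.exp(-lags / tau_grid[4]) + 0.7 * np.exp(-lags / tau_grid[9])
        coeffs, _ = fit_multiexponential(lags, g, tau_grid)
        assert coeffs[4] == pytest.approx(2.0, abs=0.02)
        assert coeffs[9] == pytest.approx(0.7, abs=0.02)

    def test_zero_lag_sum_rule(self, rng):
        tau_grid = default_tau_grid()
        lags = np.arange(0, 2000.0, 0.5)
        g = 1.3 * np.exp(-lags / 37.0) + 0.4 * np.exp(-lags / 450.0)
        coeffs, _ = fit_multiexponential(lags, g, tau_grid)
        assert np.sum(coeffs) == pytest.approx(g[0], rel=0.02)


class TestEffectiveCorrelationTime:
    def test_single_exponential(self):
        assert effective_correlation_time(np.array([2.0]), np.array([13.0])) == 13.0

    def test_equal_weight_pair(self):
        tau = effective_correlation_time(np.array([1.0, 1.0]),
                                         np.array([10.0, 30.0]))
        assert tau == pytest.approx(20.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            effective_correlation_time(np.array([0.0]), np.array([1.0]))

    def test_ou_parameter_recovery(self, rng):
        # recovery contract: variance within 10%, tau_eff within 15%;
        # series must be long relative to tau (mean-subtraction bias is
        # O(tau/T)) and the ensemble large enough to pin the slow tail
        v, tau, dt = 0.9, 40.0, 0.5
        xs = [ou_realization(np.array([v]), np.array([tau]), dt, 200_000, rng)
              for _ in range(64)]
        lags, g = empirical_covariance(((x, x) for x in xs), dt=dt,
                                       max_lag=2000.0)
        tau_grid = default_tau_grid()
        coeffs, _ = fit_multiexponential(lags, g, tau_grid)
        assert np.sum(coeffs) == pytest.approx(v, rel=0.10)
        assert effective_correlation_time(coeffs, tau_grid) == pytest.approx(
            tau, rel=0.15)


class TestSpectralDensity:
    def test_zero_frequency_is_integral(self):
        c = np.array([1.0, 2.0])
        tau = np.array([3.0, 0.5])
        assert spectral_density(c, tau, 0.0) == pytest.approx(np.sum(c * tau))

    @given(w=st.floats(-50, 50), tau=st.floats(0.1, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_single_exponential_closed_form(self, w, tau):
        c = 1.7
        j = spectral_density(np.array([c]), np.array([tau]), w)
        expected = c * tau * (1.0 + 1j * w * tau) / (1.0 + (w * tau) ** 2)
        assert j == pytest.approx(expected, rel=1e-10)

    def test_decay_at_large_frequency(self):
        c, tau = np.array([1.0]), np.array([2.0])
        mags = [abs(spectral_density(c, tau, w)) for w in (1e2, 1e4, 1e6)]
        assert mags[0] > mags[1] > mags[2]
        assert mags[2] < 1e-5

    def test_pole_rejected(self):
        with pytest.raises(ValueError):
            spectral_density(np.array([1.0]), np.array([2.0]), -1j / 2.0)

    def test_complex_argument_decay_side(self):
        # Im(ω) < 0 adds decay: finite value, no pole
        j = spectral_density(np.array([1.0]), np.array([2.0]), 1.0 - 0.5j)
        assert np.isfinite(j)


class TestCovarianceModel:
    def _model(self):
        tau_grid = default_tau_grid()
        auto = np.zeros(12)
        auto[6] = 1.0
        C = complete_eed_coefficients(auto, 0.5 * auto, 0.8 * auto,
                                      -0.2 * auto, -0.3 * auto)
        Z = C.sum(axis=-1)
        return CovarianceModel(labels=EED_LABELS, tau_grid=tau_grid,
                               coeffs=C, zero_lag=Z)

    def test_symmetry_completion(self):
        m = self._model()
        i = {lbl: k for k, lbl in enumerate(EED_LABELS)}
        assert np.array_equal(m.coeffs[i["D_XX"], i["D_XX"]],
                              m.coeffs[i["D_YY"], i["D_YY"]])
        assert np.array_equal(m.coeffs[i["D_XX"], i["D_ZZ"]],
                              m.coeffs[i["D_YY"], i["D_ZZ"]])
        assert not np.any(m.coeffs[i["D_XY"], i["D_XX"]])
        assert np.allclose(m.zero_lag, m.zero_lag.T)

    def test_roundtrip_json(self, tmp_path):
        m = self._model()
        p = tmp_path / "cov.json"
        m.to_json(p)
        m2 = CovarianceModel.from_json(p)
        assert np.allclose(m.coeffs, m2.coeffs)
        assert m.labels == m2.labels

    def test_validate_and_tau_eff(self):
        m = self._model()
        m.validate()
        assert m.tau_eff("D_XX") == pytest.approx(default_tau_grid()[6])

    def test_completed_matrix_matches_direct_estimation(self, rng):
        # build correlated (x, y, z) with y a symmetric partner of x and
        # check the completed matrix against directly estimated entries
        n = 40_000
        base = ou_realization(np.array([1.0]), np.array([20.0]), 0.5, n, rng)
        extra = ou_realization(np.array([1.0]), np.array([20.0]), 0.5, n, rng)
        x = base + 0.3 * extra
        y = base - 0.3 * extra  # same marginal statistics as x by symmetry
        lags, g_xy = empirical_covariance([(x, y)], dt=0.5, max_lag=100.0)
        _, g_yx = empirical_covariance([(y, x)], dt=0.5, max_lag=100.0)
        assert np.abs(g_xy - g_yx).max() < 0.15 * max(abs(g_xy[0]), 1e-12) + 0.1
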