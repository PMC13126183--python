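"""Covariance functions of fluctuating couplings and their spectral densities.

The relaxation superoperator is driven by the auto- and cross-covariance
functions g_{j,k}(t) = ⟨δX_j(0)·δX_k(t)⟩ of the fluctuating coupling
parameters.  Empirical covariances are estimated per trajectory (FFT
lagged products after per-trajectory mean subtraction, unbiased per-lag
normalisation) and averaged over the ensemble, then fitted by linear
least squares to a multiexponential decay on a fixed basis of 12
logarithmically spaced time constants (0.1 ns – 2 μs):

    g_{j,k}(t) ≈ Σ_n c_{j,k,n}·exp(−t/τ_n)

whose one-sided Fourier transform — the spectral density — is analytic:

    j_{j,k}(ω) = Σ_n c_{j,k,n}·τ_n / (1 − iωτ_n),   ω ∈ ℂ.

For in-plane motion only five EED covariances are independent (auto XX,
XY, ZZ; cross XX–YY, XX–ZZ); the remainder follow from symmetry.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.fft

from .observables import EED_LABELS, CouplingSeries

__all__ = [
    "default_tau_grid",
    "estimate_covariance",
    "empirical_covariance",
    "fit_multiexponential",
    "effective_correlation_time",
    "spectral_density",
    "CovarianceModel",
    "complete_eed_coefficients",
]


def default_tau_grid(n: int = 12, tau_min: float = 0.1,
                     tau_max: float = 2000.0) -> np.ndarray:
    """12 characteristic times, log-spaced 0.1 ns – 2 μs."""
    return np.geomspace(tau_min, tau_max, n)


def _lagged_products(x: np.ndarray, y: np.ndarray, n_lag: int) -> np.ndarray:
    """Σ_t x(t)·y(t+l) for l = 0..n_lag via FFT, unbiased normalisation."""
    n = x.size
    nfft = scipy.fft.next_fast_len(n + n_lag)
    fx = scipy.fft.rfft(x, nfft)
    fy = scipy.fft.rfft(y, nfft)
    s = scipy.fft.irfft(np.conj(fx) * fy, nfft)[: n_lag + 1]
    return s / (n - np.arange(n_lag + 1))


def empirical_covariance(pairs, dt: float, max_lag: float):
    """Ensemble-averaged covariance function from raw series pairs.

    ``pairs`` iterates over ``(x, y)`` arrays sampled at interval ``dt``
    (ns); each trajectory's mean is subtracted before lagged products are
    formed, products are averaged within and then across trajectories.
    Returns ``(lags, g)``.
    """
    n_lag = int(round(max_lag / dt))
    acc = None
    count = 0
    for x, y in pairs:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("mismatched series lengths")
        if n_lag >= x.size:
            raise ValueError("max_lag must be shorter than the series")
        g = _lagged_products(x - x.mean(), y - y.mean(), n_lag)
        acc = g if acc is None else acc + g
        count += 1
    if count == 0:
        raise ValueError("no series supplied")
    lags = np.arange(n_lag + 1) * dt
    return lags, acc / count


def estimate_covariance(series: list[CouplingSeries], pair: tuple[str, str],
                        max_lag: float):
    """Covariance of two labelled couplings over a trajectory ensemble."""
    if not series:
        raise ValueError("empty series collection")
    dt = float(series[0].times[1] - series[0].times[0])
    for cs in series:
        if cs.components[pair[0]].size != series[0].components[pair[0]].size:
            raise ValueError("mismatched time grids across trajectories")
    return empirical_covariance(
        ((cs.components[pair[0]], cs.components[pair[1]]) for cs in series),
        dt, max_lag,
    )


def fit_multiexponential(lags: np.ndarray, g: np.ndarray,
                         tau_grid: np.ndarray | None = None,
                         ridge: float = 1e-8):
    """Linear least-squares fit of g(t) on the fixed exponential basis.

    Coefficients are unconstrained in sign (cross-covariances and
    non-monotone decays need negative weights); a small ridge penalty
    scaled to the design norm stabilises the ill-conditioned basis.
    Returns ``(coeffs, residual_norm)``.
    """
    if tau_grid is None:
        tau_grid = default_tau_grid()
    E = np.exp(-np.asarray(lags)[:, None] / np.asarray(tau_grid)[None, :])
    G = E.T @ E
    scale = np.linalg.norm(G)
    cond = np.linalg.cond(G + ridge * scale * np.eye(len(tau_grid)))
    if cond > 1e12:
        warnings.warn(
            "ill-conditioned multiexponential design; increasing ridge",
            RuntimeWarning,
        )
        ridge = max(ridge, 1e-6)
    coeffs = np.linalg.solve(G + ridge * scale * np.eye(len(tau_grid)), E.T @ g)
    residual = float(np.linalg.norm(E @ coeffs - g))
    return coeffs, residual


def effective_correlation_time(coeffs: np.ndarray, tau_grid: np.ndarray) -> float:
    """τ_eff = Σ c_n·τ_n / Σ c_n, the integral of the normalised covariance."""
    total = float(np.sum(coeffs))
    if total <= 0:
        raise ValueError("non-positive fitted variance")
    return float(np.sum(coeffs * tau_grid) / total)


def spectral_density(coeffs: np.ndarray, tau_grid: np.ndarray, omega):
    """One-sided transform j(ω) = Σ c_n τ_n/(1 − iωτ_n) at complex ω.

    Vectorised over ``omega``; raises on a pole of the closed form.
    """
    w = np.asarray(omega, dtype=complex)
    denom = 1.0 - 1j * w[..., None] * tau_grid
    if np.any(np.abs(denom) < 1e-12):
        raise ValueError("spectral density evaluated at a pole")
    out = np.sum(coeffs * tau_grid / denom, axis=-1)
    return out if out.ndim else complex(out)


@dataclass
class CovarianceModel:
    """Multiexponential model of the coupling covariance matrix.

    ``coeffs[j, k]`` holds the 12 expansion coefficients of g_{j,k}(t)
    for the ordered ``labels``; ``zero_lag`` is the empirical covariance
    matrix at lag 0 (before fitting).
    """

    labels: tuple[str, ...]
    tau_grid: np.ndarray
    coeffs: np.ndarray  # (L, L, n_tau)
    zero_lag: np.ndarray  # (L, L) empirical
    fit_residuals: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        L = len(self.labels)
        self.tau_grid = np.asarray(self.tau_grid, dtype=float)
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.zero_lag = np.asarray(self.zero_lag, dtype=float)
        if self.coeffs.shape != (L, L, self.tau_grid.size):
            raise ValueError("coeffs shape inconsistent with labels/tau_grid")
        if self.zero_lag.shape != (L, L):
            raise ValueError("zero_lag shape inconsistent with labels")

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def covariance(self, j, k, t):
        cj = self.coeffs[self._ix(j), self._ix(k)]
        return np.sum(cj * np.exp(-np.asarray(t)[..., None] / self.tau_grid), axis=-1)

    def spectral_density(self, j, k, omega):
        return spectral_density(self.coeffs[self._ix(j), self._ix(k)],
                                self.tau_grid, omega)

    def tau_eff(self, label) -> float:
        """Effective correlation time of an autocovariance entry (ns)."""
        i = self._ix(label)
        return effective_correlation_time(self.coeffs[i, i], self.tau_grid)

    def variance(self, label) -> float:
        i = self._ix(label)
        return float(np.sum(self.coeffs[i, i]))

    def _ix(self, key) -> int:
        return key if isinstance(key, (int, np.integer)) else self.index(key)

    def validate(self, tol: float = 0.05) -> None:
        """Check Σc against the empirical zero-lag covariance."""
        recon = self.coeffs.sum(axis=-1)
        scale = np.abs(self.zero_lag).max()
        if scale > 0 and np.abs(recon - self.zero_lag).max() > tol * scale:
            raise ValueError("fitted coefficients do not reproduce zero-lag covariance")

    # -- serialization ---------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "labels": list(self.labels),
            "tau_grid_ns": self.tau_grid.tolist(),
            "coeffs": self.coeffs.tolist(),
            "zero_lag": self.zero_lag.tolist(),
            "fit_residuals": {str(k): v for k, v in self.fit_residuals.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CovarianceModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            labels=tuple(payload["labels"]),
            tau_grid=np.array(payload["tau_grid_ns"]),
            coeffs=np.array(payload["coeffs"]),
            zero_lag=np.array(payload["zero_lag"]),
            fit_residuals=payload.get("fit_residuals", {}),
        )


def complete_eed_coefficients(auto_xx, auto_zz, auto_xy, cross_xx_yy,
                              cross_xx_zz) -> np.ndarray:
    """Complete the 4×4 EED coefficient matrix from the five independent
    entries using in-plane symmetry.

    Ordering follows :data:`~zenospin.observables.EED_LABELS`:
    (D_XX, D_YY, D_ZZ, D_XY).  Symmetry relations: auto YY = auto XX,
    cross YY–ZZ = cross XX–ZZ, and D_XY is uncorrelated with every
    diagonal component.
    """
    n = len(auto_xx)
    C = np.zeros((4, 4, n))
    XX, YY, ZZ, XY = range(4)
    C[XX, XX] = C[YY, YY] = auto_xx
    C[ZZ, ZZ] = auto_zz
    C[XY, XY] = auto_xy
    C[XX, YY] = C[YY, XX] = cross_xx_yy
    C[XX, ZZ] = C[ZZ, XX] = cross_xx_zz
    C[YY, ZZ] = C[ZZ, YY] = cross_xx_zz
    return C


def build_eed_model(fits: dict, tau_grid: np.ndarray,
                    zero_lag: dict) -> CovarianceModel:
    """Assemble the EED :class:`CovarianceModel` from fitted entries.

    ``fits`` maps the five independent pair keys, e.g. ``("D_XX","D_XX")``,
    to coefficient arrays; ``zero_lag`` maps the same keys to empirical
    lag-0 values.
    """
    C = complete_eed_coefficients(
        fits[("D_XX", "D_XX")], fits[("D_ZZ", "D_ZZ")], fits[("D_XY", "D_XY")],
        fits[("D_XX", "D_YY")], fits[("D_XX", "D_ZZ")],
    )
    Z = np.zeros((4, 4))
    XX, YY, ZZ, XY = range(4)
    Z[XX, XX] = Z[YY, YY] = zero_lag[("D_XX", "D_XX")]
    Z[ZZ, ZZ] = zero_lag[("D_ZZ", "D_ZZ")]
    Z[XY, XY] = zero_lag[("D_XY", "D_XY")]
    Z[XX, YY] = Z[YY, XX] = zero_lag[("D_XX", "D_YY")]
    Z[XX, ZZ] = Z[ZZ, XX] = zero_lag[("D_XX", "D_ZZ")]
    Z[YY, ZZ] = Z[ZZ, YY] = zero_lag[("D_XX", "D_ZZ")]
    return CovarianceModel(labels=EED_LABELS, tau_grid=tau_grid, coeffs=C,
                           zero_lag=Z)
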