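"""Independent brute-force references for validating the master equation.

These implementations deliberately avoid the eigenbasis/spectral-density
machinery of :mod:`zenospin.relaxation`:

* :func:`redfield_reference` integrates the Schrödinger-picture
  second-order memory kernel −Σ∫g(τ)[A_j, e^{Lτ}[A_k, ·]]dτ at K = 0 by
  direct time-domain quadrature (no analytic transforms), the
  Redfield-class cross-check of the superoperator build.  For white
  noise it coincides with the interaction-picture Redfield tensor.
* :func:`stochastic_liouville_yield` averages explicit propagation of
  ρ(t) under Ornstein–Uhlenbeck realisations of the fluctuating
  couplings, validating the reduced master-equation description of the
  recombination yield.

Oracle results never feed production outputs; they live behind the test
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.integrate
import scipy.linalg
import scipy.signal
from numba import njit

from .relaxation import RelaxationChannel, commutation_superoperator

__all__ = [
    "NoiseRealization",
    "ou_realization",
    "stochastic_liouville_yield",
    "redfield_reference",
]


@dataclass
class NoiseRealization:
    """Sampled zero-mean processes X_i(t) matching a target covariance."""

    times: np.ndarray
    samples: np.ndarray  # (n_proc, n_steps)
    seed: int


def ou_realization(coeffs: np.ndarray, tau_grid: np.ndarray, dt: float,
                   n_steps: int, rng: np.random.Generator) -> np.ndarray:
    """One realisation of a process with autocovariance Σ c_n e^{−t/τ_n},
    built as a sum of independent OU processes using exact discrete-time
    updates (no integrator error).  Negative coefficients are rejected:
    a single-process target must be a genuine mixture."""
    coeffs = np.asarray(coeffs, dtype=float)
    if np.any(coeffs < 0):
        raise ValueError("OU mixture requires non-negative coefficients")
    x = np.zeros(n_steps)
    for c, tau in zip(coeffs, tau_grid):
        if c == 0.0:
            continue
        a = np.exp(-dt / tau)
        s = np.sqrt(c * (1.0 - a * a))
        y0 = rng.standard_normal() * np.sqrt(c)  # stationary start
        z = rng.standard_normal(n_steps - 1)
        y, _ = scipy.signal.lfilter([1.0], [1.0, -a], s * z, zi=[a * y0])
        x += np.concatenate(([y0], y))
    return x


@njit(fastmath=False)
def _propagate_realization(H, K, A_stack, X, P_s, rho0, dt, k_r, k_f):
    """RK4 propagation of dρ/dt = −i(H_eff ρ − ρ H_eff†) with
    H_eff = H + ΣX_i(t)A_i − iK; returns (∫Tr P_Sρ dt, ∫Tr ρ dt)."""
    n = H.shape[0]
    n_steps = X.shape[1]
    rho = rho0.copy()
    int_ps = 0.0
    int_tr = 0.0
    prev_ps = np.real(np.trace(P_s @ rho))
    prev_tr = np.real(np.trace(rho))
    for s in range(n_steps):
        Heff = H.copy().astype(np.complex128)
        for i in range(A_stack.shape[0]):
            Heff += X[i, s] * A_stack[i]
        Heff = Heff - 1j * K

        def _rhs(r):
            return -1j * (Heff @ r - r @ Heff.conj().T)

        k1 = _rhs(rho)
        k2 = _rhs(rho + 0.5 * dt * k1)
        k3 = _rhs(rho + 0.5 * dt * k2)
        k4 = _rhs(rho + dt * k3)
        rho = rho + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        cur_ps = np.real(np.trace(P_s @ rho))
        cur_tr = np.real(np.trace(rho))
        int_ps += 0.5 * dt * (prev_ps + cur_ps)
        int_tr += 0.5 * dt * (prev_tr + cur_tr)
        prev_ps = cur_ps
        prev_tr = cur_tr
    return int_ps, int_tr, prev_tr


def stochastic_liouville_yield(H: np.ndarray, K: np.ndarray,
                               channel: RelaxationChannel, P_s: np.ndarray,
                               rho0: np.ndarray, k_r: float, k_f: float,
                               dt: float, t_max: float, n_real: int,
                               seed: int = 0):
    """Trajectory-averaged singlet yield under explicit coupling noise.

    Each realisation draws independent OU processes for the channel's
    fluctuating variables (diagonal covariance assumed for the toy
    systems this oracle targets), propagates the non-unitary Liouville
    equation with RK4, and accumulates Φ_S = k_r·∫Tr(P_Sρ)dt.  Returns
    ``(mean, stderr)``; the residual norm of ρ(t_max) bounds the
    truncation error.

    Step-size contract: dt must resolve both the fastest coupling and the
    shortest correlation time.
    """
    tau_min = float(np.min(channel.tau_grid))
    if dt > 0.2 * tau_min:
        raise ValueError("dt must be well below the shortest correlation time")
    n_steps = int(round(t_max / dt))
    m = len(channel.operators)
    A_stack = np.array(channel.operators, dtype=complex)
    phis = np.empty(n_real)
    master = np.random.SeedSequence(seed)
    for r, child in enumerate(master.spawn(n_real)):
        rng = np.random.default_rng(child)
        X = np.empty((m, n_steps))
        for i in range(m):
            X[i] = ou_realization(channel.coeffs[i, i], channel.tau_grid, dt,
                                  n_steps, rng)
        int_ps, _, tail = _propagate_realization(
            H.astype(complex), K.astype(complex), A_stack, X,
            P_s.astype(complex), rho0.astype(complex), dt, k_r, k_f)
        phis[r] = k_r * int_ps
        if tail > 1e-3:
            raise ValueError(
                f"t_max too short: {tail:.2e} population remains at t_max")
    return float(phis.mean()), float(phis.std(ddof=1) / np.sqrt(n_real))


def redfield_reference(channels: list[RelaxationChannel], H: np.ndarray,
                       K: np.ndarray | None = None,
                       quad_tol: float = 1e-10) -> np.ndarray:
    """Second-order relaxation tensor at K = 0 by direct quadrature.

    Integrates −Σ_{j,k}∫₀^∞ dτ g_{j,k}(τ)·[A_j, e^{−iHτ}[A_k, ·]e^{iHτ}]
    using adaptive quadrature of the matrix-valued integrand in the H
    eigenbasis.  Refuses K ≠ 0 (outside the oracle's validity)."""
    if K is not None and np.any(np.abs(K) > 1e-14):
        raise ValueError("redfield_reference is only valid for K = 0")
    n = H.shape[0]
    w, U = np.linalg.eigh(H)
    N2 = n * n

    def propagator(tau):
        u = U @ np.diag(np.exp(-1j * w * tau)) @ U.conj().T  # e^{−iHτ}
        return np.kron(u.conj(), u)  # vec(u ρ u†)

    tau_max = 0.0
    pieces = []
    for ch in channels:
        comms = [commutation_superoperator(A) for A in ch.operators]
        for j in range(len(ch.operators)):
            for k in range(len(ch.operators)):
                if np.any(ch.coeffs[j, k]):
                    pieces.append((comms[j], comms[k], ch.coeffs[j, k],
                                   ch.tau_grid))
                    tau_max = max(tau_max, float(np.max(
                        ch.tau_grid[np.asarray(ch.coeffs[j, k]) != 0.0])))
    if not pieces:
        return np.zeros((N2, N2), dtype=complex)

    def integrand(tau):
        P = propagator(tau)
        out = np.zeros((N2, N2), dtype=complex)
        for Cj, Ck, c, taus in pieces:
            g = float(np.sum(c * np.exp(-tau / taus)))
            out += g * (Cj @ (P @ Ck))
        return out

    T = 40.0 * tau_max
    val, _ = scipy.integrate.quad_vec(integrand, 0.0, T, epsabs=quad_tol,
                                      epsrel=quad_tol)
    return -val
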