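"""Nakajima–Zwanzig relaxation superoperator from coupling covariances.

The Schrödinger-picture second-order relaxation superoperator

    R = −Σ_{j,k} ∫₀^∞ dτ g_{j,k}(τ) · Â_j† e^{Lτ} Â_k

(Â the commutation superoperator of the Hermitian coupling operator A,
L the recombination-dressed Liouvillian) is evaluated in the
biorthonormal eigenbasis of H_eff = H − iK, where the τ-integral reduces
to spectral densities j_{j,k}(λ_b* − λ_a) at complex eigenvalue
differences.  Because Im λ ≤ 0 these arguments only add decay, so the
multiexponential spectral densities converge for every element.

Channels: fluctuating electron–electron dipolar tensor (EED), Δg
tumbling-driven Zeeman modulation (variance ∝ B²), and optional exchange.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import MU_B_RAD_NS_MT
from .correlations import CovarianceModel, spectral_density
from .observables import EED_LABELS
from .spinsys import DIM, EffectiveHamiltonian, FieldSpec, spin_operators

__all__ = [
    "RelaxationChannel",
    "DeltaGParams",
    "eed_channel",
    "exchange_channel",
    "dg_channel",
    "liouvillian",
    "commutation_superoperator",
    "nz_superoperator",
    "vec",
    "unvec",
]


def vec(rho: np.ndarray) -> np.ndarray:
    """Column-stack a density operator (Fortran order)."""
    return rho.reshape(-1, order="F")


def unvec(v: np.ndarray) -> np.ndarray:
    n = int(round(np.sqrt(v.size)))
    return v.reshape(n, n, order="F")


def commutation_superoperator(A: np.ndarray) -> np.ndarray:
    """Matrix of ρ ↦ [A, ρ] on column-stacked operators."""
    n = A.shape[0]
    eye = np.eye(n)
    return np.kron(eye, A) - np.kron(A.T, eye)


def liouvillian(H: np.ndarray, K: np.ndarray) -> np.ndarray:
    """L(ρ) = −i[H, ρ] − {K, ρ} as a matrix on vectorised operators."""
    n = H.shape[0]
    eye = np.eye(n)
    return (
        -1j * (np.kron(eye, H) - np.kron(H.T, eye))
        - (np.kron(eye, K) + np.kron(K.T, eye))
    )


@dataclass
class RelaxationChannel:
    """Hermitian coupling operators paired with their covariance model.

    ``coeffs[j, k]`` are the multiexponential coefficients of
    g_{j,k}(t) on ``tau_grid``; the fluctuating variables have zero mean
    (their means live in the coherent Hamiltonian).
    """

    label: str
    operators: list[np.ndarray]
    coeffs: np.ndarray  # (m, m, n_tau)
    tau_grid: np.ndarray

    def __post_init__(self) -> None:
        m = len(self.operators)
        if self.coeffs.shape[:2] != (m, m):
            raise ValueError("covariance dimension does not match operator count")
        for A in self.operators:
            if not np.allclose(A, A.conj().T, atol=1e-10):
                raise ValueError("channel operators must be Hermitian")


def eed_channel(cov: CovarianceModel) -> RelaxationChannel:
    """EED fluctuation channel: symmetrised two-spin operators for the
    (XX, YY, ZZ, XY) tensor components paired with the completed
    covariance matrix.  XZ/YZ components vanish identically in 2D."""
    if tuple(cov.labels[:4]) != EED_LABELS:
        raise ValueError(f"covariance model must carry labels {EED_LABELS}")
    ops = spin_operators()
    S1, S2 = ops.S1, ops.S2
    A_ops = [
        S1[0] @ S2[0],                    # XX
        S1[1] @ S2[1],                    # YY
        S1[2] @ S2[2],                    # ZZ
        S1[0] @ S2[1] + S1[1] @ S2[0],    # XY symmetrised
    ]
    return RelaxationChannel(
        label="EED", operators=A_ops,
        coeffs=cov.coeffs[:4, :4], tau_grid=cov.tau_grid,
    )


def exchange_channel(coeffs: np.ndarray, tau_grid: np.ndarray) -> RelaxationChannel:
    """Fluctuating exchange channel with operator −(½ + 2 S₁·S₂)."""
    ops = spin_operators()
    A = -(0.5 * np.eye(DIM) + 2.0 * sum(a @ b for a, b in zip(ops.S1, ops.S2)))
    return RelaxationChannel(
        label="EXCHANGE", operators=[A],
        coeffs=np.asarray(coeffs).reshape(1, 1, -1), tau_grid=tau_grid,
    )


@dataclass(frozen=True)
class DeltaGParams:
    """Δg-relaxation inputs: per-axis variance of the fluctuating part of
    the g-matrix projection and its correlation time.

    The defaults are placeholders of a plausible magnitude; quantitative
    work should supply values derived from MD/DFT analysis of the radical
    in its membrane environment.
    """

    sigma_g2: float = 2.5e-7  # ⟨δg²⟩ per Cartesian component
    tau_c: float = 1.0  # ns

    def __post_init__(self) -> None:
        if self.sigma_g2 < 0 or self.tau_c <= 0:
            raise ValueError("invalid Delta-g parameters")


def dg_channel(params: DeltaGParams, fld: FieldSpec) -> RelaxationChannel:
    """Δg tumbling channel: independent single-electron spin components,
    zero-lag variance (μ_B·B/ħ)²·⟨δg²⟩ per component (∝ B²), one
    correlation time, radicals uncorrelated."""
    if params is None:
        raise ValueError("Delta-g channel enabled without parameters")
    ops = spin_operators()
    A_ops = [S[i] for S in (ops.S1, ops.S2) for i in range(3)]
    var = (MU_B_RAD_NS_MT * fld.B) ** 2 * params.sigma_g2
    m = len(A_ops)
    coeffs = np.zeros((m, m, 1))
    for i in range(m):
        coeffs[i, i, 0] = var
    return RelaxationChannel(
        label="DELTA_G", operators=A_ops, coeffs=coeffs,
        tau_grid=np.array([params.tau_c]),
    )


def nz_superoperator(channels: list[RelaxationChannel],
                     heff: EffectiveHamiltonian) -> np.ndarray:
    """Assemble R in the eigenbasis of H_eff and return it in the lab basis.

    For each channel, every coupling operator is transformed into the
    biorthonormal eigenbasis, the inner commutator is scaled element-wise
    by j_{j,k}(λ_b* − λ_a), and the result is closed with the outer
    commutator of A_j.  Channels and operator labels commute under the
    double sum, and cross-correlations between physically independent
    channels are zero.
    """
    n = heff.matrix.shape[0]
    N2 = n * n
    R = np.zeros((N2, N2), dtype=complex)
    if not channels:
        return R

    lam = heff.eigenvalues
    V = heff.right
    Vinv = heff.left.conj().T  # rows are left eigenvectors
    eye = np.eye(n)

    # vec(ρ̃) = vec(V⁻¹ ρ V⁻†) and back
    T_in = np.kron(Vinv.conj(), Vinv)
    T_out = np.kron(V.conj(), V)

    # Ω[a, b] = λ_b* − λ_a; vec index (a + n·b) ↔ element (a, b)
    Omega = lam.conj()[None, :] - lam[:, None]

    for ch in channels:
        m = len(ch.operators)
        A_til = [Vinv @ A @ V for A in ch.operators]
        inner = [np.kron(eye, At) - np.kron(At.conj(), eye) for At in A_til]
        for j in range(m):
            S_j = np.zeros((N2, N2), dtype=complex)
            used = False
            for k in range(m):
                c_jk = ch.coeffs[j, k]
                if not np.any(c_jk):
                    continue
                J = spectral_density(c_jk, ch.tau_grid, Omega)
                S_j += J.reshape(-1, order="F")[:, None] * inner[k]
                used = True
            if not used:
                continue
            outer = commutation_superoperator(ch.operators[j])
            R -= outer @ (T_out @ (S_j @ T_in))
    return R
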