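"""Spin Hamiltonians and kinetic operators of the radical pair.

Hilbert space: two electron spins-½ and one spin-½ nucleus (the
α-proton) per radical, ordered (e₁, e₂, n₁, n₂), dimension 16.  The
coherent Hamiltonian comprises isotropic hyperfine, (motion-averaged)
electron–electron dipolar, Zeeman and optionally exchange terms, all in
angular-frequency units (rad ns⁻¹, ħ = 1).  Spin-selective recombination
enters through the Haberkorn-type reaction operator
K = (k_r/2)·P_S + (k_f/2)·1, which combines with H into the non-Hermitian
effective Hamiltonian H_eff = H − iK whose biorthonormal eigensystem
underpins the relaxation-superoperator construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .constants import MU_B_RAD_NS_MT, G_E

__all__ = [
    "SpinSystemSpec",
    "FieldSpec",
    "EffectiveHamiltonian",
    "SpinOperators",
    "spin_operators",
    "singlet_projector",
    "triplet_projector",
    "hamiltonian",
    "reaction_operator",
    "effective_hamiltonian",
]

DIM = 16  # (2 electrons ⊗ 2 nuclei) spin-½ product space

_SX = 0.5 * np.array([[0, 1], [1, 0]], dtype=complex)
_SY = 0.5 * np.array([[0, -1j], [1j, 0]], dtype=complex)
_SZ = 0.5 * np.array([[1, 0], [0, -1]], dtype=complex)
_ID = np.eye(2, dtype=complex)


def _embed(op: np.ndarray, slot: int) -> np.ndarray:
    mats = [_ID, _ID, _ID, _ID]
    mats[slot] = op
    out = mats[0]
    for m in mats[1:]:
        out = np.kron(out, m)
    return out


@dataclass(frozen=True)
class SpinOperators:
    """Cartesian spin-½ operators on the 16-dim product space."""

    S1: tuple[np.ndarray, np.ndarray, np.ndarray]
    S2: tuple[np.ndarray, np.ndarray, np.ndarray]
    I1: tuple[np.ndarray, np.ndarray, np.ndarray]
    I2: tuple[np.ndarray, np.ndarray, np.ndarray]

    def dot(self, A: tuple, B: tuple) -> np.ndarray:
        return sum(a @ b for a, b in zip(A, B))


_OPERATORS: SpinOperators | None = None


def spin_operators() -> SpinOperators:
    """Electron and nuclear spin operators, ordering (e₁, e₂, n₁, n₂)."""
    global _OPERATORS
    if _OPERATORS is None:
        def triple(slot):
            return tuple(_embed(m, slot) for m in (_SX, _SY, _SZ))

        _OPERATORS = SpinOperators(
            S1=triple(0), S2=triple(1), I1=triple(2), I2=triple(3)
        )
    return _OPERATORS


def singlet_projector() -> np.ndarray:
    """P_S = ¼·1 − S₁·S₂ (electronic singlet, identity on the nuclei)."""
    ops = spin_operators()
    return 0.25 * np.eye(DIM, dtype=complex) - ops.dot(ops.S1, ops.S2)


def triplet_projector() -> np.ndarray:
    return np.eye(DIM, dtype=complex) - singlet_projector()


@dataclass(frozen=True)
class FieldSpec:
    """Applied magnetic field: magnitude (mT) and orientation relative to
    the membrane normal (z)."""

    B: float = 0.0
    theta: float = 0.0
    phi: float = 0.0

    def __post_init__(self) -> None:
        if self.B < 0:
            raise ValueError("B must be non-negative")
        if not 0.0 <= self.theta <= np.pi:
            raise ValueError("theta must lie in [0, pi]")
        if not 0.0 <= self.phi < 2.0 * np.pi + 1e-12:
            raise ValueError("phi must lie in [0, 2*pi)")

    def vector(self) -> np.ndarray:
        """Field vector in mT in the membrane frame."""
        st, ct = np.sin(self.theta), np.cos(self.theta)
        return self.B * np.array([st * np.cos(self.phi), st * np.sin(self.phi), ct])


def _isotropic_g() -> np.ndarray:
    return G_E * np.eye(3)


@dataclass(frozen=True)
class SpinSystemSpec:
    """Static spin-Hamiltonian and kinetic parameters.

    All couplings are angular frequencies in rad ns⁻¹ and rates in ns⁻¹.
    ``mean_dipolar`` is the trajectory-averaged dipolar tensor from the
    Brownian-dynamics stage; ``g_matrix`` defaults to the isotropic
    free-electron value (the anisotropic motion-averaged matrix is a
    configuration input).
    """

    a_iso: tuple[float, float] = (0.0, 0.0)
    g_matrix: np.ndarray = field(default_factory=_isotropic_g)
    mean_dipolar: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    k_r: float = 0.0
    k_f: float = 0.001
    J_ex0: float = 0.0
    beta: float = 5.4
    mean_J: float = 0.0

    def __post_init__(self) -> None:
        if self.k_r < 0 or self.k_f < 0:
            raise ValueError("rates must be non-negative")
        D = np.asarray(self.mean_dipolar, dtype=float)
        if D.shape != (3, 3) or not np.allclose(D, D.T, atol=1e-10):
            raise ValueError("mean_dipolar must be a symmetric 3x3 tensor")
        if abs(np.trace(D)) > 1e-8 * (1.0 + np.abs(D).max()):
            raise ValueError("mean_dipolar must be traceless")
        g = np.asarray(self.g_matrix, dtype=float)
        if g.shape != (3, 3):
            raise ValueError("g_matrix must be 3x3")
        if not np.all((np.abs(np.diag(g)) > 1.9) & (np.abs(np.diag(g)) < 2.1)):
            raise ValueError("g_matrix diagonal outside sanity bounds [1.9, 2.1]")

    def with_rates(self, k_r: float | None = None, k_f: float | None = None):
        from dataclasses import replace

        kwargs = {}
        if k_r is not None:
            kwargs["k_r"] = k_r
        if k_f is not None:
            kwargs["k_f"] = k_f
        return replace(self, **kwargs)


def hamiltonian(spec: SpinSystemSpec, fld: FieldSpec) -> np.ndarray:
    """Coherent Hamiltonian H_HFC + H_dipolar + H_Zeeman (+ H_exchange).

    The exchange convention is H_ex = −J·(½ + 2 S₁·S₂), included only
    when ``spec.mean_J`` is nonzero.
    """
    ops = spin_operators()
    H = np.zeros((DIM, DIM), dtype=complex)
    for a, S, I in ((spec.a_iso[0], ops.S1, ops.I1), (spec.a_iso[1], ops.S2, ops.I2)):
        if a != 0.0:
            H += a * ops.dot(I, S)
    D = np.asarray(spec.mean_dipolar, dtype=float)
    if np.any(D):
        if not np.allclose(D, D.T, atol=1e-10):
            raise ValueError("dipolar tensor must be symmetric")
        for i in range(3):
            for j in range(3):
                if D[i, j] != 0.0:
                    H += D[i, j] * (ops.S1[i] @ ops.S2[j])
    Bvec = fld.vector()
    if np.any(Bvec):
        gB = np.asarray(spec.g_matrix, dtype=float) @ Bvec  # mT, g-weighted
        for S in (ops.S1, ops.S2):
            for i in range(3):
                if gB[i] != 0.0:
                    H += MU_B_RAD_NS_MT * gB[i] * S[i]
    if spec.mean_J != 0.0:
        H += -spec.mean_J * (0.5 * np.eye(DIM) + 2.0 * ops.dot(ops.S1, ops.S2))
    return H


def reaction_operator(spec: SpinSystemSpec) -> np.ndarray:
    """Haberkorn reaction operator K = (k_r/2)·P_S + (k_f/2)·1."""
    if spec.k_r < 0 or spec.k_f < 0:
        raise ValueError("rates must be non-negative")
    return 0.5 * spec.k_r * singlet_projector() + 0.5 * spec.k_f * np.eye(DIM)


@dataclass
class EffectiveHamiltonian:
    """Eigensystem of H_eff = H − iK with biorthonormal left/right sets.

    ``right[:, a]`` and ``left[:, a]`` satisfy left†·right = 1; the
    eigenvalues have non-positive imaginary parts bounded by the decay
    rates in K.
    """

    matrix: np.ndarray
    eigenvalues: np.ndarray
    right: np.ndarray
    left: np.ndarray  # columns: left eigenvectors, left.conj().T @ right = 1

    def reconstruct(self) -> np.ndarray:
        return (self.right * self.eigenvalues) @ self.left.conj().T


def effective_hamiltonian(H: np.ndarray, K: np.ndarray) -> EffectiveHamiltonian:
    """Diagonalise H_eff = H − iK (H Hermitian, K Hermitian PSD)."""
    if not np.allclose(H, H.conj().T, atol=1e-10):
        raise ValueError("H must be Hermitian")
    if not np.allclose(K, K.conj().T, atol=1e-10):
        raise ValueError("K must be Hermitian")
    Heff = H - 1j * K
    lam, V = scipy.linalg.eig(Heff)
    cond = np.linalg.cond(V)
    if cond > 1e8:
        warnings.warn(
            f"near-defective effective Hamiltonian (cond={cond:.2e}); "
            "eigenbasis relaxation build may lose accuracy",
            RuntimeWarning,
        )
    Vinv = np.linalg.inv(V)
    return EffectiveHamiltonian(
        matrix=Heff, eigenvalues=lam, right=V, left=Vinv.conj().T
    )
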