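"""Singlet recombination yields, orientation averaging and MFE surfaces.

The singlet yield Φ_S(B) = k_r·∫₀^∞ Tr{P_S ρ(t, B)} dt of the
time-independent master equation dρ/dt = (L + R)ρ is computed exactly by
a single linear solve (L + R)x = −vec(ρ₀), with the escape yield
Φ_esc = k_f·∫Tr ρ dt from the same solution; Φ_S + Φ_esc = 1 serves as a
per-solve conservation check.  Yields are averaged over a uniform
(θ, φ) orientation grid of the applied field (361 points by default) and
differenced against the zero-field solve to form the magnetic field
effect ΔΦ_S(B) = Φ_S(B) − Φ_S(0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.integrate

from .relaxation import (DeltaGParams, RelaxationChannel, dg_channel,
                         eed_channel, liouvillian, nz_superoperator, unvec, vec)
from .spinsys import (DIM, FieldSpec, SpinSystemSpec, effective_hamiltonian,
                      hamiltonian, reaction_operator, singlet_projector)

__all__ = [
    "initial_state",
    "YieldSolve",
    "singlet_yield",
    "singlet_yield_propagated",
    "orientation_grid",
    "YieldResult",
    "YieldSurface",
    "orientation_averaged_yield",
    "mfe_surface",
    "fpair_percent_change",
    "diffusion_control_threshold",
]


def initial_state(kind: str) -> np.ndarray:
    """Initial density operator: ``"TRIPLET"`` → (1 − P_S)/12 (pure
    electronic triplet, nuclei maximally mixed) or ``"FPAIR"`` → 1/16
    (spin-uncorrelated encounter pair)."""
    kind = kind.upper()
    if kind == "TRIPLET":
        rho = (np.eye(DIM) - singlet_projector()) / 12.0
    elif kind == "FPAIR":
        rho = np.eye(DIM, dtype=complex) / 16.0
    else:
        raise ValueError("kind must be TRIPLET or FPAIR")
    return rho


@dataclass
class YieldSolve:
    """Result of one master-equation solve."""

    phi_s: float
    phi_escape: float

    @property
    def conservation_defect(self) -> float:
        return abs(self.phi_s + self.phi_escape - 1.0)


def singlet_yield(L: np.ndarray, R: np.ndarray, rho0: np.ndarray,
                  k_r: float, k_f: float) -> YieldSolve:
    """Φ_S = k_r·Tr(P_S·X) with X = ∫ρ dt from (L+R)X = −ρ₀."""
    M = L + R if R is not None else L
    try:
        x = np.linalg.solve(M, -vec(rho0.astype(complex)))
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular master equation; ensure k_f > 0 so all states decay"
        ) from exc
    rho_int = unvec(x)
    phi_s = float(np.real(k_r * np.trace(singlet_projector() @ rho_int)))
    phi_esc = float(np.real(k_f * np.trace(rho_int)))
    return YieldSolve(phi_s=phi_s, phi_escape=phi_esc)


def singlet_yield_propagated(L: np.ndarray, R: np.ndarray, rho0: np.ndarray,
                             k_r: float, k_f: float, t_max: float | None = None,
                             rtol: float = 1e-8, atol: float = 1e-12) -> YieldSolve:
    """Verification path: explicit time propagation with quadrature of
    Tr(P_S ρ) and Tr ρ, plus an exponential tail correction."""
    M = (L + R) if R is not None else L
    P_s = singlet_projector()
    if t_max is None:
        t_max = 50.0 / max(k_f, 1e-6)
    v_ps = vec(P_s.T.conj()).conj()  # Tr(P_S ρ) = v_ps · vec(ρ)
    v_id = vec(np.eye(DIM, dtype=complex).T)

    def rhs(t, y):
        rho = y[:-2]
        d = M @ rho
        return np.concatenate([d, [v_ps @ rho, v_id @ rho]])

    y0 = np.concatenate([vec(rho0.astype(complex)), [0.0 + 0j, 0.0 + 0j]])
    sol = scipy.integrate.solve_ivp(rhs, (0.0, t_max), y0, rtol=rtol, atol=atol,
                                    method="DOP853")
    yT = sol.y[:, -1]
    rho_T = yT[:-2]
    # tail: remaining integrals from the linear solve of the residual state
    x_tail = np.linalg.solve(M, -rho_T)
    int_ps = float(np.real(yT[-2] + v_ps @ x_tail))
    int_id = float(np.real(yT[-1] + v_id @ x_tail))
    return YieldSolve(phi_s=k_r * int_ps, phi_escape=k_f * int_id)


def orientation_grid(n: int = 361) -> list[tuple[float, float]]:
    """Cartesian product grid of field orientations: √n equally spaced
    polar angles over [0, π] times √n azimuths over [0, 2π)."""
    if n == 1:
        return [(0.0, 0.0)]
    m = int(round(np.sqrt(n)))
    if m * m != n:
        raise ValueError("orientation count must be a perfect square")
    thetas = np.linspace(0.0, np.pi, m)
    phis = np.linspace(0.0, 2.0 * np.pi, m, endpoint=False)
    return [(float(t), float(p)) for t in thetas for p in phis]


@dataclass
class YieldResult:
    """Orientation statistics of Φ_S at one (k_r, B) point."""

    mean: float
    min: float
    max: float
    per_orientation: np.ndarray
    B: float
    initial: str

    def __post_init__(self) -> None:
        if not -1e-8 <= self.mean <= 1.0 + 1e-8:
            raise ValueError("yield outside [0, 1]")


def _relaxation_channels(spec, fld, cov_model, dg_params,
                         extra_channels) -> list[RelaxationChannel]:
    channels = []
    if cov_model is not None:
        channels.append(eed_channel(cov_model))
    if dg_params is not None and fld.B > 0:
        channels.append(dg_channel(dg_params, fld))
    if extra_channels:
        channels.extend(extra_channels)
    return channels


def orientation_averaged_yield(spec: SpinSystemSpec, B: float, rho0: np.ndarray,
                               cov_model=None, dg_params: DeltaGParams | None = None,
                               n_orientations: int = 361,
                               extra_channels=None,
                               initial: str = "TRIPLET",
                               conservation_tol: float = 1e-8) -> YieldResult:
    """Solve the master equation over the orientation grid at field B (mT).

    At B = 0 the orientation of the (zero) field vector is immaterial and
    a single solve is performed.
    """
    K = reaction_operator(spec)
    grid = orientation_grid(1 if B == 0.0 else n_orientations)
    phis = np.empty(len(grid))
    for i, (theta, phi) in enumerate(grid):
        fld = FieldSpec(B=B, theta=theta, phi=phi)
        H = hamiltonian(spec, fld)
        L = liouvillian(H, K)
        channels = _relaxation_channels(spec, fld, cov_model, dg_params,
                                        extra_channels)
        if channels:
            heff = effective_hamiltonian(H, K)
            R = nz_superoperator(channels, heff)
        else:
            R = None
        sol = singlet_yield(L, R, rho0, spec.k_r, spec.k_f)
        if sol.conservation_defect > conservation_tol:
            raise RuntimeError(
                f"yield conservation violated ({sol.conservation_defect:.2e}) "
                f"at B={B}, theta={theta:.3f}, phi={phi:.3f}"
            )
        phis[i] = sol.phi_s
    return YieldResult(mean=float(phis.mean()), min=float(phis.min()),
                       max=float(phis.max()), per_orientation=phis, B=B,
                       initial=initial)


@dataclass
class YieldSurface:
    """Φ_S and ΔΦ_S over the (k_r,0 × B) grid."""

    k_r0: np.ndarray  # intrinsic contact rates (ns⁻¹)
    k_r: np.ndarray  # effective rates (ns⁻¹), ratio·k_r0
    B: np.ndarray  # field magnitudes (mT)
    phi_mean: np.ndarray  # (n_k, n_B)
    phi_min: np.ndarray
    phi_max: np.ndarray
    phi_zero: np.ndarray  # (n_k,) zero-field yields
    delta_phi: np.ndarray  # (n_k, n_B) mean MFE vs same-k zero field
    initial: str
    provenance: dict = field(default_factory=dict)


def mfe_surface(base_spec: SpinSystemSpec, k_r0_grid, B_grid, kr_ratio: float,
                cov_model=None, dg_params: DeltaGParams | None = None,
                n_orientations: int = 361, initial: str = "TRIPLET",
                progress: bool = False) -> YieldSurface:
    """Sweep (k_r,0, B): rebuild K, H_eff and R per point/orientation,
    solve, and aggregate orientation statistics and the MFE ΔΦ_S.

    ``k_r0_grid`` in ns⁻¹; effective rates are k_r = kr_ratio·k_r,0 using
    the Brownian-dynamics-derived ratio of the active geometry.
    """
    k_r0_grid = np.asarray(k_r0_grid, dtype=float)
    B_grid = np.asarray(B_grid, dtype=float)
    if k_r0_grid.size == 0 or B_grid.size == 0:
        raise ValueError("empty sweep grid")
    rho0 = initial_state(initial)
    nk, nB = k_r0_grid.size, B_grid.size
    phi_mean = np.empty((nk, nB))
    phi_min = np.empty((nk, nB))
    phi_max = np.empty((nk, nB))
    phi_zero = np.empty(nk)
    for ik, k_r0 in enumerate(k_r0_grid):
        spec = base_spec.with_rates(k_r=kr_ratio * k_r0)
        try:
            res0 = orientation_averaged_yield(
                spec, 0.0, rho0, cov_model=cov_model, dg_params=dg_params,
                n_orientations=n_orientations, initial=initial)
        except Exception as exc:  # annotate failure location
            raise RuntimeError(f"zero-field solve failed at k_r0={k_r0}") from exc
        phi_zero[ik] = res0.mean
        for ib, B in enumerate(B_grid):
            if B == 0.0:
                phi_mean[ik, ib] = phi_min[ik, ib] = phi_max[ik, ib] = res0.mean
                continue
            try:
                res = orientation_averaged_yield(
                    spec, B, rho0, cov_model=cov_model, dg_params=dg_params,
                    n_orientations=n_orientations, initial=initial)
            except Exception as exc:
                raise RuntimeError(
                    f"solve failed at k_r0={k_r0}, B={B}") from exc
            phi_mean[ik, ib] = res.mean
            phi_min[ik, ib] = res.min
            phi_max[ik, ib] = res.max
        if progress:  # pragma: no cover
            print(f"  k_r0 {ik + 1}/{nk} done")
    delta = phi_mean - phi_zero[:, None]
    delta[:, B_grid == 0.0] = 0.0
    return YieldSurface(
        k_r0=k_r0_grid, k_r=kr_ratio * k_r0_grid, B=B_grid,
        phi_mean=phi_mean, phi_min=phi_min, phi_max=phi_max,
        phi_zero=phi_zero, delta_phi=delta, initial=initial,
        provenance={"kr_ratio": kr_ratio, "n_orientations": n_orientations},
    )


def surface_to_hdf5(surface: YieldSurface, path) -> None:
    """Persist a :class:`YieldSurface` (full arrays plus provenance)."""
    import json

    import h5py

    with h5py.File(path, "w") as fh:
        for name in ("k_r0", "k_r", "B", "phi_mean", "phi_min", "phi_max",
                     "phi_zero", "delta_phi"):
            fh.create_dataset(name, data=getattr(surface, name))
        fh.attrs["initial"] = surface.initial
        fh.attrs["provenance"] = json.dumps(surface.provenance)


def fpair_percent_change(delta_phi_s: float, phi_s0: float) -> float:
    """Percentage yield change for an F-pair encounter assuming immediate
    recombination of the singlet fraction:
    100·(0.75·ΔΦ_S)/(0.25 + 0.75·Φ_S(0))."""
    if not 0.0 <= phi_s0 <= 1.0:
        raise ValueError("phi_s0 must lie in [0, 1]")
    return 100.0 * (0.75 * delta_phi_s) / (0.25 + 0.75 * phi_s0)


def diffusion_control_threshold(D: float, sigma: float, R: float,
                                beta: float) -> float:
    """Intrinsic contact rate above which 2D recombination becomes
    diffusion-controlled: k_diff·β/(2πσN_A) = D·β/(σ·ln(R/σ)), in MHz."""
    if R <= sigma:
        raise ValueError("R must exceed sigma")
    rate_ns = D * beta / (sigma * np.log(R / sigma))
    return rate_ns * 1e3  # ns⁻¹ → MHz
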