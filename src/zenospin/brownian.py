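"""Overdamped Brownian dynamics of two soft discs in a circular microdomain.

The pair of lipid peroxyl radicals is modelled as two discs of contact
distance ``sigma`` diffusing in a planar circular domain of radius
``R_domain`` (the membrane "picket-and-fence" microdomain).  Disc–disc
and disc–boundary interactions use a purely repulsive force-shifted
Lennard-Jones potential whose force and force-derivative vanish at the
cutoff r_C = σ·(26/7)^{1/6} (the inflection point of the LJ potential).

The overdamped Langevin equation dr = D·F dt + √(2D) dW (k_B T ≡ 1, so
the mobility is D itself) is integrated with a fixed-step Euler–Heun
predictor–corrector; the step is capped well below dr_max²/(4D) so the
expected diffusive displacement per step stays below ``dr_max``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "BDConfig",
    "Trajectory",
    "IntegratorError",
    "cutoff_radius",
    "shifted_force_potential",
    "sample_initial_positions",
    "simulate_pair",
    "trajectory_seed_sequence",
]

#: Soft-boundary overshoot tolerance (Å); larger excursions flag failure.
BOUNDARY_TOLERANCE = 0.5


class IntegratorError(RuntimeError):
    """Raised when the stochastic integrator produces an invalid state."""


@dataclass(frozen=True)
class BDConfig:
    """Parameters of the two-disc Brownian dynamics simulation.

    Attributes
    ----------
    sigma:
        Contact distance of the discs (Å).
    epsilon:
        Lennard-Jones well depth in units of k_B·T.
    R_domain:
        Microdomain radius (Å); ``inf`` disables the boundary.
    D_diff:
        Per-particle translational diffusion coefficient (Å² ns⁻¹).
    dr_max:
        Maximum expected diffusive displacement per step (Å).
    t_total:
        Trajectory duration (ns).
    sample_dt:
        Observable sampling interval (ns).
    n_traj:
        Number of trajectories in the ensemble.
    master_seed:
        Seed from which per-trajectory seeds are derived.
    """

    sigma: float = 9.0
    epsilon: float = 1.0
    R_domain: float = 25.0
    D_diff: float = 0.14
    dr_max: float = 0.5
    t_total: float = 20_000.0
    sample_dt: float = 0.05
    n_traj: int = 512
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.R_domain <= self.sigma:
            raise ValueError("R_domain must exceed sigma (discs must fit)")
        if self.dr_max <= 0:
            raise ValueError("dr_max must be positive")
        if self.sample_dt <= 0:
            raise ValueError("sample_dt must be positive")
        if self.D_diff <= 0:
            raise ValueError("D_diff must be positive")
        if self.t_total <= 0:
            raise ValueError("t_total must be positive")
        if self.dt_max <= 0:  # pragma: no cover - implied by the above
            raise ValueError("derived dt_max must be positive")

    @property
    def dt_max(self) -> float:
        """Step cap dr_max²/(4D) (ns)."""
        return self.dr_max**2 / (4.0 * self.D_diff)

    @property
    def r_cutoff(self) -> float:
        """Force-shifted LJ cutoff σ(26/7)^{1/6} (Å)."""
        return cutoff_radius(self.sigma)

    @property
    def n_samples(self) -> int:
        return int(round(self.t_total / self.sample_dt))

    def with_(self, **kwargs) -> "BDConfig":
        return replace(self, **kwargs)


@dataclass
class Trajectory:
    """Sampled positions of the two discs on a uniform time grid."""

    times: np.ndarray  # (n,) ns
    pos1: np.ndarray  # (n, 2) Å
    pos2: np.ndarray  # (n, 2) Å
    seed: int

    def separation(self) -> np.ndarray:
        """Inter-disc distance r₁₂(t) (Å)."""
        return np.hypot(*(self.pos1 - self.pos2).T)

    def displacement(self) -> np.ndarray:
        """Displacement vectors r₁ − r₂, shape (n, 2)."""
        return self.pos1 - self.pos2


def cutoff_radius(sigma: float) -> float:
    """Cutoff r_C = σ(26/7)^{1/6}, the LJ inflection point."""
    return sigma * (26.0 / 7.0) ** (1.0 / 6.0)


def _lj_energy_force(r: float, sigma: float, epsilon: float) -> tuple[float, float]:
    sr6 = (sigma / r) ** 6
    u = 4.0 * epsilon * (sr6**2 - sr6)
    du = 4.0 * epsilon * (-12.0 * sr6**2 + 6.0 * sr6) / r
    return u, du


def shifted_force_potential(r, cfg: BDConfig):
    """Force-shifted LJ energy and force magnitude at distance ``r``.

    Returns ``(energy, force)`` in (k_B T, k_B T Å⁻¹); the force is
    −u′_SF(r), non-negative (purely repulsive) and exactly zero for
    r ≥ r_C.  Accepts scalars or arrays.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    rc = cfg.r_cutoff
    _, du_c = _lj_energy_force(rc, cfg.sigma, cfg.epsilon)
    u_c, _ = _lj_energy_force(rc, cfg.sigma, cfg.epsilon)

    inside = r < rc
    u = np.zeros_like(r)
    f = np.zeros_like(r)
    if np.any(inside):
        ri = r[inside] if r.ndim else r
        u_lj, du_lj = _lj_energy_force(ri, cfg.sigma, cfg.epsilon)
        u_sf = u_lj - (ri - rc) * du_c - u_c
        f_sf = -(du_lj - du_c)
        if r.ndim:
            u[inside] = u_sf
            f[inside] = f_sf
        else:
            u = u_sf
            f = f_sf
    if r.ndim == 0:
        return float(u), float(f)
    return u, f


def trajectory_seed_sequence(master_seed: int, index: int) -> np.random.SeedSequence:
    """Counter-based per-trajectory seed so trajectory ``index`` is
    reproducible in isolation."""
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))


def sample_initial_positions(cfg: BDConfig, seed) -> tuple[np.ndarray, np.ndarray]:
    """Random initial placement with disc–disc and disc–boundary
    clearance of at least σ (rejection sampling, uniform measure).
    """
    rng = np.random.default_rng(seed)
    r_max = cfg.R_domain - cfg.sigma
    if not np.isfinite(cfg.R_domain):
        r_max = 10.0 * cfg.sigma  # free-space test configurations
    if r_max <= 0:
        raise ValueError("no feasible placement: R_domain - sigma <= 0")
    max_tries = 100_000  # acceptance floor 1e-4 on the pair constraint
    for _ in range(max_tries):
        u = rng.random(2)
        ang = rng.random(2) * 2.0 * np.pi
        rad = r_max * np.sqrt(u)
        p = np.stack([rad * np.cos(ang), rad * np.sin(ang)], axis=1)
        if np.hypot(*(p[0] - p[1])) >= cfg.sigma:
            return p[0].copy(), p[1].copy()
    raise ValueError(
        "initial-placement acceptance below 1e-4: domain too crowded "
        f"(R_domain={cfg.R_domain}, sigma={cfg.sigma})"
    )


@njit(fastmath=False)
def _forces(x, sigma, epsilon, rc, du_c, R, boundary):
    f = np.zeros(4)
    dx = x[0] - x[2]
    dy = x[1] - x[3]
    r = math.sqrt(dx * dx + dy * dy)
    if epsilon != 0.0 and r < rc:
        sr6 = (sigma / r) ** 6
        du = 4.0 * epsilon * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
        fmag = -(du - du_c)  # repulsive, >= 0
        fx = fmag * dx / r
        fy = fmag * dy / r
        f[0] += fx
        f[1] += fy
        f[2] -= fx
        f[3] -= fy
    if boundary:
        for i in range(2):
            px = x[2 * i]
            py = x[2 * i + 1]
            d = math.sqrt(px * px + py * py)
            gap = R - d
            if d > 1e-12 and gap < rc:
                if gap < 0.05 * sigma:
                    gap = 0.05 * sigma  # clamp the wall singularity
                sr6 = (sigma / gap) ** 6
                du = 4.0 * epsilon * (-12.0 * sr6 * sr6 + 6.0 * sr6) / gap
                fmag = -(du - du_c)
                f[2 * i] -= fmag * px / d
                f[2 * i + 1] -= fmag * py / d
    return f


@njit(fastmath=False)
def _heun_run(x0, dt, n_sub, n_samp, noise_scale, sigma, epsilon, rc, du_c, R,
              boundary, D, seed):
    out = np.empty((n_samp + 1, 4))
    out[0] = x0
    x = x0.copy()
    np.random.seed(seed)
    for s in range(n_samp):
        for _ in range(n_sub):
            w = np.empty(4)
            for i in range(4):
                w[i] = np.random.normal() * noise_scale
            f0 = _forces(x, sigma, epsilon, rc, du_c, R, boundary)
            xp = x + D * dt * f0 + w
            f1 = _forces(xp, sigma, epsilon, rc, du_c, R, boundary)
            x = x + 0.5 * D * dt * (f0 + f1) + w
        out[s + 1] = x
    return out


def simulate_pair(cfg: BDConfig, seed) -> Trajectory:
    """Integrate one trajectory of the confined radical pair.

    ``seed`` may be an integer or a :class:`numpy.random.SeedSequence`;
    identical (cfg, seed) yields a bit-identical trajectory.
    """
    if isinstance(seed, np.random.SeedSequence):
        seq = seed
    else:
        seq = np.random.SeedSequence(int(seed))
    # one 32-bit word drives the in-kernel RNG
    kernel_seed = int(seq.generate_state(1, dtype=np.uint32)[0])
    init_seq = np.random.SeedSequence(entropy=seq.entropy, spawn_key=seq.spawn_key + (1,))

    p1, p2 = sample_initial_positions(cfg, init_seq)
    x0 = np.array([p1[0], p1[1], p2[0], p2[1]])

    dt_cap = cfg.dt_max / 4.0
    n_sub = max(1, int(math.ceil(cfg.sample_dt / dt_cap)))
    dt = cfg.sample_dt / n_sub
    noise_scale = math.sqrt(2.0 * cfg.D_diff * dt)

    boundary = bool(np.isfinite(cfg.R_domain))
    R = cfg.R_domain if boundary else 0.0
    rc = cfg.r_cutoff
    _, du_c = _lj_energy_force(rc, cfg.sigma, max(cfg.epsilon, 1e-300))
    if cfg.epsilon == 0.0:
        du_c = 0.0

    n_samp = cfg.n_samples
    out = _heun_run(
        x0, dt, n_sub, n_samp, noise_scale, cfg.sigma, cfg.epsilon, rc, du_c,
        R, boundary, cfg.D_diff, kernel_seed,
    )

    if not np.all(np.isfinite(out)):
        bad = int(np.argmax(~np.all(np.isfinite(out), axis=1)))
        raise IntegratorError(
            f"non-finite position at sample {bad} (t={bad * cfg.sample_dt} ns); "
            f"state={out[bad]!r}"
        )
    if boundary:
        radii = np.hypot(out[:, 0], out[:, 1])
        radii = np.maximum(radii, np.hypot(out[:, 2], out[:, 3]))
        worst = float(radii.max())
        if worst > cfg.R_domain + BOUNDARY_TOLERANCE:
            raise IntegratorError(
                f"boundary overshoot {worst - cfg.R_domain:.3f} Å exceeds "
                f"tolerance {BOUNDARY_TOLERANCE} Å"
            )
    times = np.arange(n_samp + 1) * cfg.sample_dt
    return Trajectory(times=times, pos1=out[:, :2], pos2=out[:, 2:], seed=kernel_seed)


def simulate_ensemble(cfg: BDConfig):
    """Yield ``cfg.n_traj`` trajectories with counter-based seeds."""
    for k in range(cfg.n_traj):
        yield simulate_pair(cfg, trajectory_seed_sequence(cfg.master_seed, k))


def pair_distance_density(cfg: BDConfig, r_grid: np.ndarray,
                          n_quad: int = 201) -> np.ndarray:
    """Equilibrium pair-distance density p(r) by numerical quadrature.

    Boltzmann weight exp(−u_SF(r)) times the geometric two-body measure
    A(r) = ∫dr₁ w(|r₁|) ∫dφ w(|r₁ + r·ê(φ)|), with w the wall weight
    exp(−u_SF(R−|x|)).  Returned density is normalised on ``r_grid``.
    """
    R = cfg.R_domain
    s_grid = np.linspace(0.0, R, n_quad)
    phi_grid = np.linspace(0.0, 2.0 * np.pi, n_quad)

    def wall_weight(d):
        gap = np.clip(R - d, 1e-6, None)
        u, _ = shifted_force_potential(gap, cfg)
        return np.exp(-u)

    w1 = wall_weight(s_grid)
    dens = np.zeros_like(r_grid)
    for i, r in enumerate(r_grid):
        if r <= 0:
            continue
        u_pair, _ = shifted_force_potential(r, cfg)
        if u_pair > 500:
            continue
        # |r1 + r e(phi)| over the (s, phi) grid
        s = s_grid[:, None]
        d2 = s**2 + r**2 + 2.0 * s * r * np.cos(phi_grid)[None, :]
        w2 = wall_weight(np.sqrt(d2))
        inner = np.trapezoid(w2, phi_grid, axis=1)
        A = np.trapezoid(s_grid * w1 * inner, s_grid)
        dens[i] = r * np.exp(-u_pair) * A
    norm = np.trapezoid(dens, r_grid)
    return dens / norm
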