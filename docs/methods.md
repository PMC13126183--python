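# Methods

This note records the model, the numerical choices, and the limits of
what the synthetic (simulated) inputs can demonstrate.

## Physical model

**Geometry and motion.** The radical pair is two soft discs of contact
distance σ confined to a circular planar microdomain of radius R,
representing a lipid-raft-scale compartment of the membrane. Both discs
obey overdamped Langevin dynamics dr = D·F dt + √(2D) dW per particle,
with the mobility fixed by the diffusion coefficient through the
Einstein relation (internal units Å, ns, k_BT = 1, so γ = 1/D and
temperature never appears separately). Disc–disc and disc–boundary
forces derive from the force-shifted Lennard-Jones potential
u_SF(r) = u_LJ(r) − (r − r_C)u′_LJ(r_C) − u_LJ(r_C) for r < r_C and 0
beyond; the cutoff r_C = σ(26/7)^{1/6} is the inflection point of u_LJ,
which makes the force vanish at r_C with a continuous derivative and
leaves the interaction purely repulsive. The boundary enters only
through this soft potential evaluated at the gap R − |r_i| (no hard
reflection). D is interpreted as the per-particle diffusion coefficient
(the relative coordinate then diffuses with 2D); this is one of two
readings of the model's single-D convention and is configurable.

**Spin system.** Sixteen-dimensional Hilbert space: two electron
spins-½ and one spin-½ α-proton per radical (additional hyperfine
couplings in these radicals are much weaker and omitted). The coherent
Hamiltonian holds the isotropic hyperfine term a_iso Î·Ŝ per radical,
the motion-averaged EED tensor S₁·⟨D⟩·S₂, the Zeeman term
μ_B/ħ Ŝ·g·B, and optionally a mean exchange term −J(½ + 2Ŝ₁·Ŝ₂) (the
operator convention is ours; the sign is configurable and the default
J = 0 as exchange decays much faster with distance than EED).
Spin-selective chemistry is the Haberkorn operator
K = (k_r/2)P_S + (k_f/2)1: singlet-only recombination at the
motion-averaged rate k_r plus spin-independent escape (chain
propagation) at k_f. All couplings are angular frequencies in rad ns⁻¹;
MHz inputs are linear frequencies times 2π. The dipolar prefactor
(μ₀/4π)g_e²μ_B²/ħ = 327.0 rad ns⁻¹ Å³ (≈ 2π × 52.04 MHz nm³) and the
electron gyromagnetic ratio are derived from CODATA constants at import
time, never hard-coded.

**Fluctuations and relaxation.** Diffusion modulates the EED tensor,
k_r and J. The in-plane geometry leaves four fluctuating EED entries
(XX, YY, ZZ, XY; XZ/YZ vanish identically) with five independent
covariance functions — auto XX (=YY), auto ZZ, auto XY, cross XX–YY,
cross XX–ZZ — the rest following from symmetry. These feed the
Schrödinger-picture Nakajima–Zwanzig relaxation superoperator
R = −Σ_{jk} ∫₀^∞ g_{jk}(τ) Â_j† e^{Lτ} Â_k dτ, evaluated in the
biorthonormal eigenbasis of H_eff = H − iK where the τ-integral becomes
the analytic spectral density j_{jk}(λ_b* − λ_a); since Im λ ≤ 0 the
complex arguments only add decay and every element converges. Â† is
taken as the commutation superoperator of Â† (= Â for the Hermitian
couplings used here). Unlike interaction-picture Redfield theory, the
kernel propagates under the full recombination-dressed Liouvillian,
which is what makes the construction usable in the fast-recombination
(quantum Zeno) regime. Δg relaxation — tumbling-driven modulation of
the anisotropic g-matrix — is parameterised generically as independent
single-electron spin channels whose zero-lag variance is
(μ_B B/ħ)²⟨δg²⟩ with one correlation time per radical; the default
⟨δg²⟩ = 2.5×10⁻⁷ and τ_c = 1 ns are placeholders of plausible magnitude
and quantitative work must supply values derived for the actual radical
(the B² scaling and the sign of the resulting high-field MFE are
independent of them). Cross-correlations between the EED and Δg
channels are set to zero (independent physical origins: inter-radical
geometry versus single-radical tumbling). The fluctuating part of k_r
is deliberately not a relaxation channel: a second-order treatment of
reaction-operator fluctuations is unreliable precisely at the fast
rates of interest here.

**Yields.** For the time-independent master equation the singlet yield
is exact from one linear solve, Φ_S = k_r Tr{P_S X} with
(L + R)X = −ρ(0); the escape yield k_f Tr X from the same solve gives
the per-solve conservation check Φ_S + Φ_esc = 1 (enforced to 10⁻⁸).
Explicit time propagation is retained as a verification path only.
Orientation averaging uses the Cartesian product of 19 equally spaced
polar angles on [0, π] and 19 azimuths on [0, 2π) — 361 orientations,
plain (unweighted) mean/min/max; at B = 0 one solve suffices. Initial
states: pure triplet (1 − P_S)/12 (the magnetosensitive subpopulation)
or F-pair 1/16. The F-pair percentage effect assumes immediate
recombination of the singlet quarter:
100·(0.75·ΔΦ_S)/(0.25 + 0.75·Φ_S(0)).

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| σ | 9 | Å | contact distance (hexagonal lipid packing) |
| ϵ | 1 | k_BT | soft-repulsion strength |
| R | 25 | Å | microdomain radius (raft scale; 20–35 explored) |
| D | 0.14 | Å²ns⁻¹ | per-particle diffusion coefficient |
| β | 5.4 | Å⁻¹ | decay of k_r(r) and J(r); chosen so the 2D diffusion-control threshold D·β/(σ·ln(R/σ)) is 82 MHz for the baseline geometry |
| a_iso/2π | 10.3 | MHz | α-proton hyperfine coupling (13ze isomer; 13.5 for the alternative) |
| k_f | 1 | μs⁻¹ | spin-independent escape rate |
| k_r,0 | swept | μs⁻¹ | intrinsic contact recombination rate; effective k_r = ratio·k_r,0 with ratio ≈ 0.02 recomputed from the active geometry |
| dr_max | 0.5 | Å | step cap via dt_max = dr_max²/4D |

## Numerical choices

- **Integrator.** Fixed-step Euler–Heun (predictor–corrector, additive
  noise) at dt = min(sample_dt, dt_max/4). The stationary statistics are
  what the spin stage consumes, and the equilibrium pair-distance
  density is verified against direct 2D quadrature of the Boltzmann
  weight, which is the property that licenses the fixed-step choice.
  Per-trajectory seeds derive from the master seed by a counter-based
  scheme, so any trajectory is reproducible in isolation and runs are
  bit-identical under (config, seed).
- **Ensemble scales.** "desk": 512 × 20 μs at 0.05 ns sampling (all
  shipped tests and the acceptance script); "production": 4096 × 50 μs at
  0.01 ns. A 1 μs burn-in is discarded because the initial placement is
  uniform-with-exclusion rather than Boltzmann.
- **Covariance estimation.** FFT lagged products with unbiased per-lag
  normalisation, averaged over the ensemble; lags to 2 μs on a 0.5 ns
  grid (subsampling is unbiased for the retained lags and leaves the
  zero-lag variance untouched). The pipeline centres fluctuations on
  the ensemble mean: per-trajectory centring removes slow covariance
  components and biases effective correlation times down by
  O(τ_eff/t_total) — about 40% at 20 μs trajectories for this system —
  whereas the generic `estimate_covariance` operation keeps the
  conventional per-trajectory behaviour for series whose baseline may
  drift. Means and the rate ratio ⟨e^{−β(r−σ)}⟩ use every 0.05 ns
  sample, since contact statistics are fast.
- **Multiexponential fit.** Linear least squares on the fixed basis of
  12 log-spaced τ_n (0.1 ns – 2 μs), uniform lag weighting, coefficients
  free in sign (cross-covariances need negative weights), stabilised by
  a ridge of 10⁻⁸ relative to the design norm. τ_eff ≡ Σcτ/Σc, the
  integral of the normalised covariance. Recovery on synthetic OU
  targets is accurate to ~10% provided the series are ≫ 100 τ long; the
  Σcτ functional is the noise-sensitive one, which is why the estimator
  bias above matters.
- **Superoperator build.** R is assembled once per (orientation, B,
  k_r) tuple from the eigendecomposition of H_eff (dense 16×16 eig;
  conditioning monitored with a warning fallback) and 256×256 matrix
  algebra; channel and operator ordering are exchangeable by
  construction. The linear solve uses LAPACK directly; k_f > 0
  guarantees invertibility.
- **Degenerate inputs.** Zero separation, non-square orientation
  counts, negative rates, non-symmetric dipolar tensors, spectral-
  density poles and crowded initial placements all raise explicit
  errors; boundary overshoot beyond 0.5 Å or non-finite states abort
  the integrator with diagnostics.

## What the synthetic data does and does not show

The Brownian generator *is* the study system — there is no external
data. It emulates confined lateral diffusion of two disc-like radicals
with realistic σ, D and R, and produces the fluctuation statistics
(variances, correlation times, rate ratio) that drive the spin stage.
It does not emulate membrane undulations, radical shape or internal
flexibility, hydrodynamic interactions, rotational diffusion (subsumed
in the Δg channel parameters), three-radical encounters, or the
peroxidation chain kinetics around the termination step. Passing tests
therefore demonstrate the correctness and internal consistency of the
method — including the quantum-Zeno enhancement and the
relaxation-mechanism sign — for the stated model, not quantitative
predictions for any particular membrane; those additionally require
system-specific g-matrix/Δg covariances and rate parameters.

## Design choices on genuinely open points

- τ_eff is defined as the integral of the normalised covariance
  (Σcτ/Σc); other conventions (1/e times, slowest-mode times) give
  different numbers for multi-component decays.
- β is not directly observable here; it is fixed by back-solving the
  diffusion-control criterion (82 MHz threshold) and exposed as a
  first-class parameter.
- The g-matrix defaults to isotropic g_e; the motion-averaged
  anisotropic matrix and the Δg covariance amplitudes are configuration
  inputs.
- The mean dipolar tensor frame and the g-frame are taken co-aligned
  with the membrane normal (configurable).
- Yield statistics over orientations use the plain grid mean (no sin θ
  weight), matching the uniform (θ, φ) sampling convention of the
  orientation average.

## Known limitations

- The desk-scale effective correlation time of the D_ZZ component
  (~0.10 μs) is robust under finer integration steps, longer lag
  windows and alternative centring, so reported values reflect the
  model as implemented; see the acceptance output for the numbers the
  package actually computes.
- The NZ superoperator is second-order in the system–bath coupling;
  outside the motional-narrowing regime its accuracy must be judged
  against the stochastic-Liouville oracle (the shipped toy comparison
  agrees to within two standard errors).
- Fluctuating-k_r decoherence is out of scope (see above); a stochastic
  Schrödinger treatment would be required.
- The F-pair formula assumes instantaneous recombination of the singlet
  fraction at first contact, which is an upper-bound idealisation for
  moderate k_r,0.
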