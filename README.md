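# zenospin

Magnetic field effects (MFEs) on the recombination of lipid peroxyl
radical pairs in membrane microdomains, computed by
Brownian-dynamics-informed spin dynamics.

Lipid peroxidation terminates when two peroxyl radicals (LO₂•) meet and
recombine — a spin-selective reaction that only proceeds from the
electronic singlet state of the pair. Through the radical pair
mechanism, weak magnetic fields can bias singlet–triplet interconversion
and hence the termination yield. Within a membrane, however, the two
radicals are never static: they diffuse inside a confined microdomain
("pickets and fences" picture), so the electron–electron dipolar (EED)
coupling, the exchange coupling and the recombination rate all fluctuate
with the inter-radical distance. Strong, fluctuating inter-radical
coupling normally suppresses magnetosensitivity — unless recombination
is fast enough to invoke the quantum Zeno effect.

This package quantifies that interplay for users in spin chemistry and
quantum biology. It is a pipeline of five stages:

1. **Brownian dynamics** (`zenospin.brownian`) — two soft discs
   (force-shifted Lennard-Jones, cutoff r_C = σ(26/7)^{1/6}) in a
   circular 2D domain, integrated from the overdamped Langevin equation
   dr = D·F dt + √(2D) dW (k_BT ≡ 1).
2. **Coupling observables** (`zenospin.observables`) — time series of
   the EED tensor D(r) = −(μ₀/4π)(g_e²μ_B²/ħ) r⁻³ (3êêᵀ − 1), the
   instantaneous recombination rate k_r(t) = k_r,0·e^{−β(r−σ)} and the
   exchange coupling, plus their trajectory means.
3. **Covariance models** (`zenospin.correlations`) — auto/cross
   covariances g_{jk}(t) of the fluctuating couplings, fitted as
   g_{jk}(t) = Σ_n c_{jkn} e^{−t/τ_n} on 12 log-spaced τ_n
   (0.1 ns – 2 μs), with analytic spectral densities
   j_{jk}(ω) = Σ_n c_{jkn} τ_n/(1 − iωτ_n) valid at complex ω.
4. **Master equation** (`zenospin.spinsys`, `zenospin.relaxation`) —
   dρ/dt = −i[H, ρ] − {K, ρ} + Rρ on the 16-dimensional space of two
   electrons and one α-proton per radical, with the Haberkorn reaction
   operator K = (k_r/2)P_S + (k_f/2)1 and the Nakajima–Zwanzig
   relaxation superoperator R = −Σ_{jk}∫₀^∞ g_{jk}(τ) Â_j† e^{Lτ} Â_k dτ
   evaluated via spectral densities at eigenvalue differences of
   H_eff = H − iK. Channels: EED fluctuations and Δg tumbling
   (variance ∝ B²); exchange optional.
5. **Yields** (`zenospin.yields`) — singlet recombination yield
   Φ_S(B) = k_r ∫₀^∞ Tr{P_S ρ(t)} dt by a single linear solve, averaged
   over a 361-point field-orientation grid, and the MFE
   ΔΦ_S(B) = Φ_S(B) − Φ_S(0) swept over (k_r,0 × B).

Independent brute-force references (stochastic-Liouville averaging over
explicit Ornstein–Uhlenbeck noise, time-domain quadrature of the
relaxation kernel) live in `zenospin.oracles` and are used only by the
test suite.

## Worked example

Simulate the baseline system (microdomain radius R = 25 Å, diffusion
coefficient D = 0.14 Å² ns⁻¹, contact distance σ = 9 Å, ϵ = 1 k_BT,
a_iso/2π = 10.3 MHz, k_f = 1 μs⁻¹) at the reduced "desk" scale of 512
trajectories × 20 μs, then evaluate the low-field MFE in the quantum
Zeno regime:

```python
import numpy as np
from zenospin.pipeline import desk_config, run_bd_ensemble, build_spin_spec
from zenospin.yields import (orientation_averaged_yield, initial_state,
                             fpair_percent_change)

summary = run_bd_ensemble(desk_config(master_seed=1))   # ~2 min
print(summary.kr_ratio)                       # 0.0200
print(summary.cov_model.tau_eff("D_XX"))      # 131.5 ns
print(np.diag(summary.mean_dipolar))          # [-0.0557 -0.0523  0.108] rad/ns

spec = build_spin_spec(summary, k_r0=20.0)    # k_r0 = 2e4 us^-1 (Zeno regime)
rho0 = initial_state("TRIPLET")
r0 = orientation_averaged_yield(spec, 0.0, rho0, cov_model=summary.cov_model)
r1 = orientation_averaged_yield(spec, 1.0, rho0, cov_model=summary.cov_model,
                                n_orientations=81)
print(r0.mean)                                # 0.5395
print(r1.mean, r1.min, r1.max)                # 0.6350 0.5150 0.6786
print(fpair_percent_change(r1.mean - r0.mean, r0.mean))   # 10.93
```

Reading the output: contact recombination is diluted by diffusion to an
effective rate k_r ≈ 0.02·k_r,0; the D_XX component of the dipolar
tensor decorrelates in ≈ 0.13 μs; the motion-averaged dipolar tensor is
axial about the membrane normal. In the fast-recombination (quantum
Zeno) regime a 1 mT field raises the orientation-averaged singlet yield
from 0.540 to 0.635 — for a spin-uncorrelated encounter pair (F-pair)
this is a ≈ 11% change in termination probability, despite a mean
dipolar coupling that dwarfs the hyperfine interaction.

The same workflow is scriptable from the shell (`zenospin run`,
`simulate-bd`, `fit-cov`, `yields`, `sweep`); see `zenospin --help`.
The full production preset uses 4096 trajectories × 50 μs at
0.01 ns sampling.

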