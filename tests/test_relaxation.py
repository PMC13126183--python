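"""Relaxation superoperator: channels, NZ build, limits."""

import numpy as np
import pytest

from conftest import random_hermitian, two_electron_system
from zenospin.correlations import CovarianceModel, complete_eed_coefficients, \
    default_tau_grid
from zenospin.observables import EED_LABELS
from zenospin.oracles import redfield_reference
from zenospin.relaxation import (DeltaGParams, RelaxationChannel,
                                 commutation_superoperator, dg_channel,
                                 eed_channel, liouvillian, nz_superoperator,
                                 unvec, vec)
from zenospin.spinsys import (DIM, FieldSpec, SpinSystemSpec,
                              effective_hamiltonian, hamiltonian,
                              reaction_operator, spin_operators)


def _toy_channel(rng, n=4, n_ops=2):
    ops = [random_hermitian(n, rng) for _ in range(n_ops)]
    tau = np.array([0.8, 3.0])
    coeffs = np.zeros((n_ops, n_ops, 2))
    for i in range(n_ops):
        coeffs[i, i] = [0.05 / (i + 1), 0.02]
    if n_ops > 1:
        coeffs[0, 1] = coeffs[1, 0] = [0.01, 0.005]
    return RelaxationChannel("TOY", ops, coeffs, tau)


def _eed_cov_model(scale=1.0):
    tau_grid = default_tau_grid()
    auto = np.zeros(12)
    auto[7] = 0.02 * scale
    C = complete_eed_coefficients(auto, 0.4 * auto, 0.9 * auto,
                                  -0.8 * auto, -0.2 * auto)
    return CovarianceModel(labels=EED_LABELS, tau_grid=tau_grid, coeffs=C,
                           zero_lag=C.sum(axis=-1))


class TestLiouvillian:
    def test_action_matches_commutators(self, rng):
        H = random_hermitian(DIM, rng)
        K = random_hermitian(DIM, rng)
        K = K @ K.conj().T  # PSD
        L = liouvillian(H, K)
        rho = random_hermitian(DIM, rng)
        out = unvec(L @ vec(rho))
        expected = -1j * (H @ rho - rho @ H) - (K @ rho + rho @ K)
        assert np.abs(out - expected).max() < 1e-10


class TestChannels:
    def test_eed_channel_operators(self):
        cov = _eed_cov_model()
        ch = eed_channel(cov)
        ops = spin_operators()
        expected_xy = ops.S1[0] @ ops.S2[1] + ops.S1[1] @ ops.S2[0]
        assert np.allclose(ch.operators[3], expected_xy)
        for A in ch.operators:
            assert np.allclose(A, A.conj().T)
        assert np.allclose(ch.coeffs.sum(-1), ch.coeffs.sum(-1).T.swapaxes(0, 1))

    def test_zero_covariance_gives_zero_superoperator(self):
        cov = _eed_cov_model(scale=0.0)
        ch = eed_channel(cov)
        spec = SpinSystemSpec(a_iso=(0.1, 0.1), k_r=0.1, k_f=0.01)
        H = hamiltonian(spec, FieldSpec(B=1.0))
        heff = effective_hamiltonian(H, reaction_operator(spec))
        R = nz_superoperator([ch], heff)
        assert np.abs(R).max() == 0.0

    def test_dg_channel_b2_scaling(self):
        params = DeltaGParams(sigma_g2=1e-6, tau_c=2.0)
        ch1 = dg_channel(params, FieldSpec(B=1.0))
        ch2 = dg_channel(params, FieldSpec(B=2.0))
        assert np.allclose(ch2.coeffs, 4.0 * ch1.coeffs)
        ch0 = dg_channel(params, FieldSpec(B=0.0))
        assert not np.any(ch0.coeffs)

    def test_operator_count_covariance_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            RelaxationChannel("BAD", [random_hermitian(4, rng)],
                              np.zeros((2, 2, 1)), np.array([1.0]))

    def test_non_hermitian_operator_rejected(self, rng):
        A = rng.normal(size=(4, 4)) + 1j * rng.normal(size=(4, 4))
        with pytest.raises(ValueError):
            RelaxationChannel("BAD", [A], np.zeros((1, 1, 1)), np.array([1.0]))


class TestNZSuperoperator:
    def test_matches_brute_force_kernel_at_k_zero(self, rng):
        H = random_hermitian(4, rng)
        ch = _toy_channel(rng)
        heff = effective_hamiltonian(H, np.zeros((4, 4)))
        R = nz_superoperator([ch], heff)
        R_ref = redfield_reference([ch], H)
        assert np.abs(R - R_ref).max() < 1e-6 * np.abs(R_ref).max()

    def test_trace_preservation_at_k_zero(self, rng):
        H = random_hermitian(4, rng)
        ch = _toy_channel(rng)
        heff = effective_hamiltonian(H, np.zeros((4, 4)))
        R = nz_superoperator([ch], heff)
        rho = random_hermitian(4, rng)
        assert abs(np.trace(unvec(R @ vec(rho)))) < 1e-12
        ident = vec(np.eye(4, dtype=complex))
        assert np.abs(R @ ident).max() < 1e-12

    def test_white_noise_limit_is_lindblad(self, rng):
        # τ → 0 at fixed c·τ: R → Σ γ (AρA − ½{A²,ρ}), γ = 2cτ
        H = random_hermitian(4, rng)
        A = random_hermitian(4, rng)
        gamma = 0.7
        heff = effective_hamiltonian(H, np.zeros((4, 4)))
        eye = np.eye(4)
        A2 = A @ A
        lind = gamma * (np.kron(A.conj(), A)
                        - 0.5 * (np.kron(eye, A2) + np.kron(A2.T, eye)))
        errs = []
        for tau in (1e-3, 1e-4):
            ch = RelaxationChannel(
                "W", [A], np.array([[[gamma / (2 * tau)]]]), np.array([tau]))
            R = nz_superoperator([ch], heff)
            errs.append(np.abs(R - lind).max() / np.abs(lind).max())
        assert errs[1] < errs[0]  # converges as τ → 0
        assert errs[1] < 5e-3

    def test_single_spin_longitudinal_rate_closed_form(self):
        # transverse noise on a Zeeman-split spin-½ at K = 0:
        # d⟨Sz⟩/dt = −Re j(ω0)·⟨Sz⟩ with j(ω) = cτ/(1 − iωτ)
        Sx = 0.5 * np.array([[0, 1], [1, 0]], complex)
        Sz = 0.5 * np.diag([1.0, -1.0]).astype(complex)
        w0, c, tau = 2.0, 0.3, 0.7
        ch = RelaxationChannel("T", [Sx], np.array([[[c]]]), np.array([tau]))
        heff = effective_hamiltonian(w0 * Sz, np.zeros((2, 2)))
        M = liouvillian(w0 * Sz, np.zeros((2, 2))) + nz_superoperator([ch], heff)
        out = unvec(M @ vec(Sz))
        rate = -np.real(np.trace(Sz @ out)) / np.real(np.trace(Sz @ Sz))
        assert rate == pytest.approx(c * tau / (1 + (w0 * tau) ** 2), rel=1e-10)

    def test_channel_and_operator_order_invariance(self, rng):
        H = random_hermitian(4, rng)
        K = random_hermitian(4, rng)
        K = 0.05 * (K @ K.conj().T)
        heff = effective_hamiltonian(H, K)
        cha = _toy_channel(rng)
        chb = _toy_channel(rng, n_ops=1)
        R1 = nz_superoperator([cha, chb], heff)
        R2 = nz_superoperator([chb, cha], heff)
        assert np.abs(R1 - R2).max() < 1e-12 * max(np.abs(R1).max(), 1.0)
        # permuting operator labels (with the covariance permuted the same
        # way) leaves the sum unchanged
        perm = [1, 0]
        cov_p = cha.coeffs[np.ix_(perm, perm)]
        cha_p = RelaxationChannel("TOYP", [cha.operators[i] for i in perm],
                                  cov_p, cha.tau_grid)
        R3 = nz_superoperator([cha_p, chb], heff)
        assert np.abs(R1 - R3).max() < 1e-12 * max(np.abs(R1).max(), 1.0)

    def test_full_16dim_build_matches_oracle_at_k_zero(self, rng):
        # one EED operator pair on the real spin system
        spec = SpinSystemSpec(a_iso=(0.06, 0.06),
                              mean_dipolar=np.diag([0.05, 0.05, -0.1]))
        H = hamiltonian(spec, FieldSpec(B=0.5, theta=0.9, phi=0.4))
        ops = spin_operators()
        A = ops.S1[2] @ ops.S2[2]
        ch = RelaxationChannel("EEDzz", [A], np.array([[[0.01]]]),
                               np.array([5.0]))
        heff = effective_hamiltonian(H, np.zeros((DIM, DIM)))
        R = nz_superoperator([ch], heff)
        R_ref = redfield_reference([ch], H, quad_tol=1e-9)
        assert np.abs(R - R_ref).max() < 1e-6 * np.abs(R_ref).max()

    def test_redfield_oracle_refuses_nonzero_k(self, rng):
        ch = _toy_channel(rng)
        with pytest.raises(ValueError):
            redfield_reference([ch], random_hermitian(4, rng), K=np.eye(4))

    def test_no_channels_zero(self, rng):
        heff = effective_hamiltonian(random_hermitian(4, rng), np.zeros((4, 4)))
        assert np.abs(nz_superoperator([], heff)).max() == 0.0
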