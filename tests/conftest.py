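import numpy as np
import pytest

from zenospin.brownian import BDConfig


@pytest.fixture(scope="session")
def baseline_cfg() -> BDConfig:
    """Baseline microdomain geometry at a short test duration."""
    return BDConfig(sigma=9.0, epsilon=1.0, R_domain=25.0, D_diff=0.14,
                    t_total=2000.0, sample_dt=0.05, n_traj=8, master_seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def two_electron_system():
    """4-dim two-electron toy: spin operators and singlet projector."""
    sx = 0.5 * np.array([[0, 1], [1, 0]], complex)
    sy = 0.5 * np.array([[0, -1j], [1j, 0]], complex)
    sz = 0.5 * np.diag([1.0, -1.0]).astype(complex)
    eye = np.eye(2)
    S1 = [np.kron(s, eye) for s in (sx, sy, sz)]
    S2 = [np.kron(eye, s) for s in (sx, sy, sz)]
    P_s = 0.25 * np.eye(4) - sum(a @ b for a, b in zip(S1, S2))
    return S1, S2, P_s


def random_hermitian(n, rng):
    M = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
    return (M + M.conj().T) / 2.0
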