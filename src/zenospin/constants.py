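"""Physical constants and unit conversions.

Internal unit system: lengths in Å, times in ns, energies in units of
k_B·T (so the thermal energy never appears explicitly), angular
frequencies in rad ns⁻¹ and magnetic fields in mT.  All values are
derived from CODATA constants via :mod:`scipy.constants` at import time
rather than hard-coded.
"""

from __future__ import annotations

import math

from scipy import constants as _codata

#: Free-electron g-factor (positive convention).
G_E: float = abs(_codata.value("electron g factor"))

_MU_B = _codata.value("Bohr magneton")  # J/T
_HBAR = _codata.hbar  # J s
_MU_0 = _codata.mu_0  # N/A^2

#: Bohr magneton over ħ in rad ns⁻¹ mT⁻¹ (multiply by g and B/mT to get
#: a Zeeman angular frequency).
MU_B_RAD_NS_MT: float = _MU_B / _HBAR * 1e-9 * 1e-3

#: Electron gyromagnetic ratio g_e·μ_B/ħ in rad ns⁻¹ mT⁻¹
#: (≈ 2π × 28.02 MHz/mT).
GAMMA_E_RAD_NS_MT: float = G_E * MU_B_RAD_NS_MT

#: Point-dipole coupling prefactor (μ0/4π)·g_e²·μ_B²/ħ in rad ns⁻¹ Å³.
#: The inter-electron dipolar tensor is −C/r³·(3êêᵀ − 1) with r in Å.
DIPOLAR_PREFACTOR_RAD_NS_A3: float = (
    _MU_0 / (4.0 * math.pi) * G_E**2 * _MU_B**2 / _HBAR * 1e30 * 1e-9
)


def mhz_to_rad_ns(f_mhz: float) -> float:
    """Convert a linear frequency in MHz to an angular one in rad ns⁻¹."""
    return 2.0 * math.pi * f_mhz * 1e-3


def rad_ns_to_mhz(omega: float) -> float:
    """Convert an angular frequency in rad ns⁻¹ to a linear one in MHz."""
    return omega / (2.0 * math.pi) * 1e3
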