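"""Unit system and physical constants.

Internal units are Å (length), fs (time) and amu (mass) throughout; spectroscopic
frequencies are reported in cm^-1. All conversions funnel through this module so
unit handling lives in exactly one place.
"""

from __future__ import annotations

import numpy as np

#: speed of light in cm/s (exact, SI definition)
SPEED_OF_LIGHT_CM_S = 2.99792458e10

#: 1 fs^-1 expressed in wavenumbers: 1e15 / c[cm/s] ≈ 33356.41 cm^-1
INV_FS_TO_CM1 = 1.0e15 / SPEED_OF_LIGHT_CM_S

#: Boltzmann constant in amu·Å²/fs²/K  (1.380649e-23 J/K ÷ 1.66053906660e-27 kg·(Å/fs)²)
KB_AMU_A2_FS2 = 1.380649e-23 / (1.66053906660e-27 * 1.0e10)

#: 1 amu·Å²/fs² in joule, for reference
AMU_A2_FS2_TO_J = 1.66053906660e-17


def omega_to_wavenumber(omega: float | np.ndarray) -> float | np.ndarray:
    """Angular frequency in rad/fs → wavenumber in cm^-1."""
    return omega / (2.0 * np.pi) * INV_FS_TO_CM1


def wavenumber_to_omega(nu_cm1: float | np.ndarray) -> float | np.ndarray:
    """Wavenumber in cm^-1 → angular frequency in rad/fs."""
    return nu_cm1 / INV_FS_TO_CM1 * 2.0 * np.pi


def frequency_to_wavenumber(nu_fs: float | np.ndarray) -> float | np.ndarray:
    """Ordinary frequency in fs^-1 → wavenumber in cm^-1."""
    return nu_fs * INV_FS_TO_CM1


def wavenumber_to_frequency(nu_cm1: float | np.ndarray) -> float | np.ndarray:
    """Wavenumber in cm^-1 → ordinary frequency in fs^-1."""
    return nu_cm1 / INV_FS_TO_CM1
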