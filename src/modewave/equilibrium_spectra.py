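"""Equilibrium vibrational spectra from velocity autocorrelation functions.

The mode-resolved vibrational density of states is obtained the classical way:
the autocorrelation of a mode velocity is cosine-transformed (the spectrum of a
real, even correlation function is real), after a taper that suppresses
truncation ringing and ×4 zero padding that interpolates the peak position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import correlate

from .constants import INV_FS_TO_CM1

__all__ = ["PowerSpectrum", "autocorrelation", "power_spectrum", "peak_wavenumber"]

#: supported taper windows (applied to the positive-lag half of the ACF)
TAPERS = ("hann", "blackman", "none")


@dataclass
class PowerSpectrum:
    """Non-negative power on an ascending, uniform wavenumber grid (cm^-1)."""

    wavenumbers: np.ndarray  # cm^-1, ascending, uniform
    power: np.ndarray  # arbitrary units, >= 0
    resolution: float  # cm^-1 per bin
    mode_id: int | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.wavenumbers.shape != self.power.shape:
            raise ValueError("wavenumber and power grids differ in length")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


def autocorrelation(signal: np.ndarray, max_lag: int) -> np.ndarray:
    """Unbiased autocorrelation C(τ) = (1/(T−τ)) Σ_t x(t)·x(t+τ), τ = 0..max_lag."""
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    T = len(x)
    if max_lag >= T:
        raise ValueError(f"max_lag {max_lag} must be < signal length {T}")
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    full = correlate(x, x, mode="full", method="fft")
    c = full[T - 1 : T + max_lag]
    return c / (T - np.arange(max_lag + 1))


def _taper(n: int, name: str) -> np.ndarray:
    if name == "hann":
        return np.hanning(2 * n - 1)[n - 1 :]
    if name == "blackman":
        return np.blackman(2 * n - 1)[n - 1 :]
    if name == "none":
        return np.ones(n)
    raise ValueError(f"unknown taper {name!r}; supported: {', '.join(TAPERS)}")


def power_spectrum(
    acf: np.ndarray,
    dt: float,
    window: str = "hann",
    pad_factor: int = 4,
    mode_id: int | None = None,
) -> PowerSpectrum:
    """Cosine transform of a tapered, zero-padded autocorrelation.

    S(ν_k) = w₀C₀ + 2 Σ_{τ≥1} w(τ)C(τ) cos(2π ν_k τ dt), clipped at zero; the
    abscissa runs from 0 to the Nyquist wavenumber 1/(2 dt) in cm^-1.
    """
    c = np.asarray(acf, dtype=float)
    if c.ndim != 1 or len(c) < 8:
        raise ValueError("autocorrelation series must be 1-D with length >= 8")
    if not dt > 0:
        raise ValueError("dt must be positive")
    cw = c * _taper(len(c), window)
    nfft = 2 * (pad_factor * len(c) // 2)  # even padded length
    spec = 2.0 * np.fft.rfft(cw, n=nfft).real - cw[0]
    wavenumbers = np.fft.rfftfreq(nfft, d=dt) * INV_FS_TO_CM1
    return PowerSpectrum(
        wavenumbers=wavenumbers,
        power=np.maximum(spec, 0.0),
        resolution=float(wavenumbers[1] - wavenumbers[0]),
        mode_id=mode_id,
    )


def peak_wavenumber(spectrum: PowerSpectrum, min_cm1: float = 0.0) -> float:
    """Wavenumber (cm^-1) of the spectrum's global maximum at or above ``min_cm1``."""
    mask = spectrum.wavenumbers >= min_cm1
    idx = np.flatnonzero(mask)[np.argmax(spectrum.power[mask])]
    return float(spectrum.wavenumbers[idx])
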