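"""Continuous Morlet wavelet transform of mode-velocity signals.

The transform W(a, b) = (1/√a) ∫ x(t) ψ*((t−b)/a) dt localizes a signal in time
(translation b) and frequency (scale a, inversely proportional to frequency).
The mother wavelet is the Morlet function ψ(t) = π^(−1/4) e^(iω₀t) e^(−t²/2)
without the small admissibility correction, which is below 1e-7 for the default
ω₀ = 6. The scale↔frequency map uses the centre-frequency convention
ν(a) = ω₀ / (2π a), reported in cm^-1.

The production path evaluates the transform by FFT over a zero-padded signal;
``cwt_direct`` is a brute-force evaluation of the same discretized integral,
kept as an independent reference path for correctness checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import INV_FS_TO_CM1, wavenumber_to_frequency

__all__ = [
    "MorletParams",
    "WaveletSpectrogram",
    "morlet_mother",
    "cwt",
    "cwt_direct",
    "average_power",
    "band_intensity",
    "half_rise_time",
]

_PI_M14 = np.pi ** (-0.25)


@dataclass
class MorletParams:
    """Morlet CWT parameters.

    omega0 is the dimensionless centre frequency of the mother wavelet (≥ 5 so
    the admissibility correction is negligible); the frequency grid spans
    [freq_min, freq_max] cm^-1 with ``n_scales`` points, logarithmically spaced
    by default (uniform relative resolution).
    """

    omega0: float = 6.0
    n_scales: int = 150
    freq_min: float = 50.0
    freq_max: float = 2000.0
    spacing: str = "log"

    def __post_init__(self) -> None:
        if self.omega0 < 5:
            raise ValueError(f"omega0 must be >= 5, got {self.omega0}")
        if not 0 < self.freq_min < self.freq_max:
            raise ValueError(
                f"need 0 < freq_min < freq_max, got {self.freq_min}, {self.freq_max}"
            )
        if self.n_scales < 2:
            raise ValueError("n_scales must be >= 2")
        if self.spacing not in ("log", "linear"):
            raise ValueError(f"spacing must be 'log' or 'linear', got {self.spacing!r}")

    def frequency_grid(self) -> np.ndarray:
        """Wavenumber grid in cm^-1, descending (ascending scale)."""
        if self.spacing == "log":
            grid = np.geomspace(self.freq_min, self.freq_max, self.n_scales)
        else:
            grid = np.linspace(self.freq_min, self.freq_max, self.n_scales)
        return grid[::-1].copy()

    def scales(self) -> np.ndarray:
        """Scale parameter a in fs for each grid frequency (ascending)."""
        nu_fs = wavenumber_to_frequency(self.frequency_grid())
        return self.omega0 / (2.0 * np.pi * nu_fs)


@dataclass
class WaveletSpectrogram:
    """|W(ν, t)|² power with frequency (cm^-1, descending) and time (fs) axes.

    ``coi[n]`` is the largest trustworthy row index at time column n: rows below
    it (lower frequency, larger scale) are within the e-folding distance √2·a of
    a signal edge and therefore edge-contaminated. −1 means no row is trusted.
    """

    frequencies: np.ndarray  # cm^-1, descending
    times: np.ndarray  # fs
    power: np.ndarray  # (n_freq, n_time), >= 0
    coi: np.ndarray  # (n_time,), int
    mode_id: int | None = None
    coefficients: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (len(self.frequencies), len(self.times)):
            raise ValueError(
                f"power shape {self.power.shape} inconsistent with axes "
                f"({len(self.frequencies)}, {len(self.times)})"
            )
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        self.coi = np.asarray(self.coi, dtype=int)

    @property
    def trust_mask(self) -> np.ndarray:
        """Boolean (n_freq, n_time) mask of cells inside the cone of influence."""
        rows = np.arange(len(self.frequencies))[:, None]
        return rows <= self.coi[None, :]

    def normalized(self) -> "WaveletSpectrogram":
        """Power rescaled to a maximum of 1 (arbitrary-units convention)."""
        peak = self.power.max()
        scale = 1.0 / peak if peak > 0 else 1.0
        return WaveletSpectrogram(
            frequencies=self.frequencies,
            times=self.times,
            power=self.power * scale,
            coi=self.coi,
            mode_id=self.mode_id,
        )


def morlet_mother(t: float | np.ndarray, omega0: float = 6.0) -> complex | np.ndarray:
    """Morlet mother wavelet ψ(t) = π^(−1/4) e^(iω₀t) e^(−t²/2) at rescaled time t."""
    t = np.asarray(t, dtype=float)
    out = _PI_M14 * np.exp(1j * omega0 * t - 0.5 * t * t)
    return out if out.ndim else complex(out)


def _validate_signal(signal: np.ndarray, dt: float, params: MorletParams) -> np.ndarray:
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be a 1-D series")
    if len(x) < 8:
        raise ValueError(f"signal too short for a CWT: {len(x)} < 8 frames")
    nyquist_cm1 = 0.5 / dt * INV_FS_TO_CM1
    if params.freq_max > nyquist_cm1:
        raise ValueError(
            f"freq_max {params.freq_max:.1f} cm^-1 exceeds the Nyquist wavenumber "
            f"{nyquist_cm1:.1f} cm^-1 at dt = {dt} fs"
        )
    return x


def _coi_indices(scales: np.ndarray, n: int, dt: float) -> np.ndarray:
    """Per-column largest trustworthy row: √2·a within the distance to both edges."""
    dist = np.minimum(np.arange(n), n - 1 - np.arange(n)) * dt
    return np.searchsorted(np.sqrt(2.0) * scales, dist, side="right") - 1


def cwt(
    signal: np.ndarray,
    dt: float,
    params: MorletParams | None = None,
    times: np.ndarray | None = None,
    mode_id: int | None = None,
    keep_coefficients: bool = True,
) -> WaveletSpectrogram:
    """Morlet CWT power map of a uniformly sampled signal.

    Discretizes W(a, b) = (1/√a) Σ_t x(t) ψ*((t−b)/a) dt and evaluates it for
    all translations at once by frequency-domain multiplication over the signal
    zero-padded to the next power of two ≥ twice its length (so the circular
    convolution equals the plain sum). Edge-contaminated cells are flagged in
    the cone of influence rather than trimmed.
    """
    params = params or MorletParams()
    x = _validate_signal(signal, dt, params)
    n = len(x)
    scales = params.scales()  # fs, ascending
    pad = 1 << max(int(2 * n - 1).bit_length(), 3)
    X = np.fft.fft(x, pad)
    lag = (np.arange(pad) + pad // 2) % pad - pad // 2  # signed lag per index
    u = lag * dt
    arg = u[None, :] / scales[:, None]
    # conj(ψ(−u/a)) = π^(−1/4) e^(+iω₀u/a) e^(−u²/(2a²))
    kernels = _PI_M14 * np.exp(1j * params.omega0 * arg - 0.5 * arg * arg)
    W = np.fft.ifft(X[None, :] * np.fft.fft(kernels, axis=1), axis=1)[:, :n]
    W *= (dt / np.sqrt(scales))[:, None]
    t_axis = np.arange(n) * dt if times is None else np.asarray(times, dtype=float)
    return WaveletSpectrogram(
        frequencies=params.frequency_grid(),
        times=t_axis,
        power=np.abs(W) ** 2,
        coi=_coi_indices(scales, n, dt),
        mode_id=mode_id,
        coefficients=W if keep_coefficients else None,
    )


def cwt_direct(
    signal: np.ndarray,
    dt: float,
    params: MorletParams | None = None,
) -> np.ndarray:
    """Brute-force evaluation of the discretized CWT sum at every (scale, b).

    Reference path: O(n_scales · n²), no FFT, no padding tricks. Returns the
    complex coefficient matrix on the same (descending-frequency, time) grid as
    :func:`cwt`, whose FFT path must agree with this one to rounding.
    """
    params = params or MorletParams()
    x = _validate_signal(signal, dt, params)
    n = len(x)
    t = np.arange(n) * dt
    W = np.empty((params.n_scales, n), dtype=complex)
    for row, a in enumerate(params.scales()):
        for col in range(n):
            s = (t - t[col]) / a
            W[row, col] = (dt / np.sqrt(a)) * np.sum(
                x * np.conj(morlet_mother(s, params.omega0))
            )
    return W


def average_power(spectrograms: list[WaveletSpectrogram]) -> WaveletSpectrogram:
    """Elementwise mean power over an ensemble; COI takes the least trustworthy bound."""
    if not spectrograms:
        raise ValueError("need at least one spectrogram")
    ref = spectrograms[0]
    for s in spectrograms[1:]:
        if not (
            np.array_equal(s.frequencies, ref.frequencies)
            and np.array_equal(s.times, ref.times)
        ):
            raise ValueError("spectrogram axes differ; cannot average")
    return WaveletSpectrogram(
        frequencies=ref.frequencies,
        times=ref.times,
        power=np.mean([s.power for s in spectrograms], axis=0),
        coi=np.minimum.reduce([s.coi for s in spectrograms]),
        mode_id=ref.mode_id,
    )


def band_intensity(
    spec: WaveletSpectrogram, center: float, halfwidth: float
) -> np.ndarray:
    """Per-time trapezoidal integral of power over [center−halfwidth, center+halfwidth] cm^-1."""
    rows = np.flatnonzero(np.abs(spec.frequencies - center) <= halfwidth)
    if len(rows) == 0:
        raise ValueError(
            f"band {center}±{halfwidth} cm^-1 contains no grid frequency"
        )
    if len(rows) == 1:
        return spec.power[rows[0]].copy()
    f = spec.frequencies[rows][::-1]  # ascending for integration
    p = spec.power[rows][::-1]
    return np.trapezoid(p, x=f, axis=0)


def half_rise_time(
    times: np.ndarray,
    series: np.ndarray,
    plateau_window: tuple[float, float],
) -> float:
    """Time at which a rising band series first crosses half its plateau level.

    The plateau is the mean of ``series`` over ``plateau_window`` (fs); the
    crossing is linearly interpolated between samples.
    """
    times = np.asarray(times, dtype=float)
    series = np.asarray(series, dtype=float)
    lo, hi = plateau_window
    sel = (times >= lo) & (times <= hi)
    if not sel.any():
        raise ValueError("plateau window contains no samples")
    half = 0.5 * series[sel].mean()
    above = np.flatnonzero(series >= half)
    if len(above) == 0:
        raise ValueError("series never reaches half the plateau level")
    i = above[0]
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    y0, y1 = series[i - 1], series[i]
    return float(t0 + (half - y0) / (y1 - y0) * (t1 - t0))
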