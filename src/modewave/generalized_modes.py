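"""Generalized vibrational modes from the velocity covariance matrix.

The covariance matrix of the mass-weighted atomic velocities,
K_ij = ⟨q̇_i q̇_j⟩ (raw second moment, time-averaged over the trajectory),
is symmetric positive semi-definite. Its eigenvectors, collected column-wise in
the orthogonal matrix L, define collective coordinates whose velocities are
mutually uncorrelated over the averaging window — generalized modes. Unlike
Hessian normal modes they require no quadratic potential, so they remain defined
for anharmonic motion at any temperature. Each mode is assigned a frequency from
the spectral peak of its projected velocity Q̇_α(t) = (Lᵀ q̇(t))_α.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .constants import INV_FS_TO_CM1
from .equilibrium_spectra import autocorrelation, peak_wavenumber, power_spectrum
from .errors import DimensionMismatchError, ResolutionWarning
from .trajectory_io import MassWeightedVelocitySeries

__all__ = [
    "CovarianceMatrix",
    "ModeSet",
    "ModeVelocitySeries",
    "compute_covariance",
    "diagonalize",
    "project",
    "assign_frequencies",
]


@dataclass
class CovarianceMatrix:
    """Symmetric PSD matrix K_ij = ⟨q̇_i q̇_j⟩, units amu·Å²/fs²."""

    K: np.ndarray
    n_frames_used: int
    atom_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        if self.K.ndim != 2 or self.K.shape[0] != self.K.shape[1]:
            raise ValueError(f"K must be square, got shape {self.K.shape}")
        scale = max(np.abs(self.K).max(), 1e-300)
        if np.abs(self.K - self.K.T).max() > 1e-12 * scale:
            raise ValueError("K is not symmetric within 1e-12 relative")

    @property
    def dim(self) -> int:
        return self.K.shape[0]

    @property
    def trace(self) -> float:
        return float(np.trace(self.K))


@dataclass
class ModeSet:
    """Orthonormal mode vectors (columns of L) with eigenvalues and frequencies.

    Eigenvalues are the per-mode velocity variances in amu·Å²/fs², sorted
    descending; ``frequencies`` holds the assigned wavenumber in cm^-1 per mode
    (NaN where undefined, e.g. a zero-variance mode).
    """

    L: np.ndarray
    eigenvalues: np.ndarray
    frequencies: np.ndarray | None = None
    atom_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        n = self.L.shape[1]
        if self.L.ndim != 2 or len(self.eigenvalues) != n:
            raise ValueError("L and eigenvalues disagree on mode count")
        gram = self.L.T @ self.L
        if np.abs(gram - np.eye(n)).max() > 1e-10:
            raise ValueError("mode vectors are not orthonormal within 1e-10")
        if np.any(np.diff(self.eigenvalues) > 1e-10 * max(self.eigenvalues[0], 1e-300)):
            raise ValueError("eigenvalues must be sorted descending")
        if np.any(self.eigenvalues < 0):
            raise ValueError("eigenvalues must be non-negative")
        if self.frequencies is not None:
            self.frequencies = np.asarray(self.frequencies, dtype=float)
            if len(self.frequencies) != n:
                raise ValueError("frequencies length differs from mode count")

    @property
    def n_modes(self) -> int:
        return self.L.shape[1]

    def frequency_order(self) -> np.ndarray:
        """Stable ordering of mode indices by ascending frequency (NaN last)."""
        if self.frequencies is None:
            raise ValueError("frequencies not assigned yet")
        key = np.where(np.isnan(self.frequencies), np.inf, self.frequencies)
        return np.argsort(key, kind="stable")

    def degenerate_blocks(self, rel_tol: float = 1e-8) -> list[list[int]]:
        """Group modes whose eigenvalues coincide within ``rel_tol`` relative."""
        blocks: list[list[int]] = [[0]]
        scale = max(self.eigenvalues[0], 1e-300)
        for i in range(1, self.n_modes):
            if self.eigenvalues[i - 1] - self.eigenvalues[i] <= rel_tol * scale:
                blocks[-1].append(i)
            else:
                blocks.append([i])
        return blocks

    def composition(self) -> np.ndarray:
        """Per-atom displacement weight per mode: w[a, α] = Σ_k L[3a+k, α]²."""
        n_atoms = self.L.shape[0] // 3
        return (self.L**2).reshape(n_atoms, 3, self.n_modes).sum(axis=1)

    def save(self, path: str | Path) -> None:
        """Archive to an .npz container (L, eigenvalues, frequencies, atom_order)."""
        np.savez(
            path,
            L=self.L,
            eigenvalues=self.eigenvalues,
            frequencies=(
                np.full(self.n_modes, np.nan)
                if self.frequencies is None
                else self.frequencies
            ),
            atom_order=np.array(self.atom_order, dtype="U4"),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ModeSet":
        with np.load(path) as npz:
            freq = npz["frequencies"]
            return cls(
                L=npz["L"],
                eigenvalues=npz["eigenvalues"],
                frequencies=None if np.all(np.isnan(freq)) else freq,
                atom_order=[str(s) for s in npz["atom_order"]],
            )


@dataclass
class ModeVelocitySeries:
    """Time series Q̇(t) of projected mode velocities, units √amu·Å/fs."""

    times: np.ndarray  # fs, uniform, starting at 0
    values: np.ndarray  # (n_frames, n_modes)
    mode_ids: np.ndarray | None = None
    trajectory_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != self.values.shape[0]:
            raise ValueError("times and values disagree on frame count")
        if self.mode_ids is None:
            self.mode_ids = np.arange(self.values.shape[1])
        else:
            self.mode_ids = np.asarray(self.mode_ids, dtype=int)
            if len(self.mode_ids) != self.values.shape[1]:
                raise ValueError("mode_ids length differs from number of columns")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_modes(self) -> int:
        return self.values.shape[1]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def column(self, mode_id: int) -> np.ndarray:
        """The velocity series of one mode, selected by mode id."""
        where = np.flatnonzero(self.mode_ids == mode_id)
        if len(where) == 0:
            raise KeyError(f"mode id {mode_id} not present in this series")
        return self.values[:, where[0]]


def _resolve_window(n_frames: int, frame_range: tuple[int, int] | None) -> slice:
    if frame_range is None:
        return slice(0, n_frames)
    lo, hi = frame_range
    lo = max(lo, 0)
    hi = min(hi, n_frames)
    return slice(lo, hi)


def compute_covariance(
    series: MassWeightedVelocitySeries,
    frame_range: tuple[int, int] | None = None,
) -> CovarianceMatrix:
    """Raw second-moment covariance K_ij = (1/T) Σ_t q̇_i(t) q̇_j(t).

    No mean subtraction is performed: the matrix is the literal time average of
    the velocity outer product (with centre-of-mass removal the mean velocity is
    ~0 anyway). Symmetrized as (K + Kᵀ)/2 against rounding.
    """
    win = _resolve_window(series.n_frames, frame_range)
    v = series.values[win]
    if v.shape[0] < 2:
        raise ValueError(
            f"covariance window must contain >= 2 frames, got {v.shape[0]}"
        )
    K = v.T @ v / v.shape[0]
    K = 0.5 * (K + K.T)
    return CovarianceMatrix(K=K, n_frames_used=v.shape[0], atom_order=list(series.atom_order))


def diagonalize(cov: CovarianceMatrix) -> ModeSet:
    """Eigen-decompose K into a ModeSet.

    Modes are ordered by descending eigenvalue (velocity variance). Each
    column's sign is fixed so its largest-magnitude entry is positive, making
    mode-composition reports reproducible. Tiny negative eigenvalues inside the
    numerical PSD floor are clamped to zero.
    """
    K = cov.K
    floor = -1e-10 * max(cov.trace, 0.0) / max(cov.dim, 1)
    evals, evecs = np.linalg.eigh(K)
    if evals.min() < floor - 1e-300:
        raise ValueError(
            f"K has negative eigenvalue {evals.min():.3e} beyond the PSD floor"
        )
    evals = np.clip(evals, 0.0, None)
    order = np.argsort(evals, kind="stable")[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    for col in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, col]))
        if evecs[i, col] < 0:
            evecs[:, col] = -evecs[:, col]
    return ModeSet(L=evecs, eigenvalues=evals, atom_order=list(cov.atom_order))


def project(
    series: MassWeightedVelocitySeries, modes: ModeSet
) -> ModeVelocitySeries:
    """Mode velocities Q̇(t) = Lᵀ q̇(t), one row per frame."""
    if series.values.shape[1] != modes.L.shape[0]:
        raise DimensionMismatchError(
            f"series has {series.values.shape[1]} components but modes expect "
            f"{modes.L.shape[0]}"
        )
    return ModeVelocitySeries(
        times=series.times - series.times[0],
        values=series.values @ modes.L,
    )


def assign_frequencies(
    modes: ModeSet,
    series: MassWeightedVelocitySeries,
    max_lag: int | None = None,
    taper: str = "hann",
    pad_factor: int = 4,
    resolution_tol_cm1: float | None = None,
) -> ModeSet:
    """Assign each mode the wavenumber of its velocity power-spectrum maximum.

    A zero-variance mode gets NaN. If the achievable resolution 1/(T dt) is
    coarser than ``resolution_tol_cm1`` a ResolutionWarning is recorded and the
    assignment is still performed.
    """
    qdot = project(series, modes)
    dt = series.dt
    T = qdot.n_frames
    if resolution_tol_cm1 is not None:
        achievable = INV_FS_TO_CM1 / (T * dt)
        if achievable > resolution_tol_cm1:
            warnings.warn(
                f"window supports {achievable:.2f} cm^-1 resolution, coarser than "
                f"the requested {resolution_tol_cm1:.2f} cm^-1",
                ResolutionWarning,
                stacklevel=2,
            )
    lag = max_lag if max_lag is not None else max(T // 2, 8)
    lag = min(lag, T - 1)
    var_floor = 1e-14 * max(modes.eigenvalues.max(initial=0.0), 1e-300)
    freqs = np.empty(modes.n_modes)
    for alpha in range(modes.n_modes):
        x = qdot.values[:, alpha]
        if x.var() + x.mean() ** 2 <= var_floor:
            freqs[alpha] = np.nan
            continue
        spec = power_spectrum(
            autocorrelation(x, lag), dt, window=taper, pad_factor=pad_factor
        )
        freqs[alpha] = peak_wavenumber(spec)
    return replace(modes, frequencies=freqs)
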