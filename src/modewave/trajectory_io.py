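"""Trajectory containers and extended-XYZ I/O.

The on-disk format is multi-frame extended XYZ: every frame is a header line with
the atom count, a comment line (optionally carrying an ``ase``-style
``Properties=species:S:1:pos:R:3:vel:R:3`` declaration) and one line per atom with
the element symbol, the Cartesian position in Å and, optionally, the velocity in
Å/fs. A plain 7-column dialect (symbol x y z vx vy vz) without a Properties tag is
accepted as well.

Mass weighting follows the flattening convention ``index = 3*a + k`` for atom ``a``
(0-based) and Cartesian component ``k`` ∈ {x, y, z}; that single order is used by
every downstream module (covariance indices, mode-vector components).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    InsufficientDataError,
    TrajectoryFormatError,
    UnknownElementError,
)
from .masses import STANDARD_ATOMIC_WEIGHTS

__all__ = [
    "Trajectory",
    "MassTable",
    "MassWeightedVelocitySeries",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "estimate_velocities",
    "mass_weight",
]

_PROPERTIES_RE = re.compile(r"Properties=(\S+)", re.IGNORECASE)


class MassTable:
    """Mapping from chemical symbol to atomic mass in amu.

    Parameters
    ----------
    masses:
        Symbol → mass mapping. All masses must be positive.
    """

    def __init__(self, masses: dict[str, float]):
        bad = {s: m for s, m in masses.items() if not m > 0}
        if bad:
            raise ValueError(f"non-positive masses for symbols {sorted(bad)}")
        self._masses = dict(masses)

    @classmethod
    def standard(cls) -> "MassTable":
        """Built-in standard atomic weights."""
        return cls(STANDARD_ATOMIC_WEIGHTS)

    @classmethod
    def from_file(cls, path: str | Path, base: "MassTable | None" = None) -> "MassTable":
        """Read a two-column (symbol, mass) text file; '#' starts a comment.

        Entries override ``base`` (defaults to the standard table).
        """
        merged = dict((base or cls.standard())._masses)
        for ln, raw in enumerate(Path(path).read_text().splitlines()):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln + 1}: expected 'symbol mass', got {raw!r}")
            merged[parts[0]] = float(parts[1])
        return cls(merged)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._masses

    def mass_of(self, symbol: str) -> float:
        try:
            return self._masses[symbol]
        except KeyError:
            raise UnknownElementError(
                f"element symbol {symbol!r} has no mass in the table"
            ) from None

    def masses_for(self, elements: Sequence[str]) -> np.ndarray:
        """Per-atom mass array (amu) for an element list."""
        return np.array([self.mass_of(s) for s in elements], dtype=float)


@dataclass
class Trajectory:
    """Ordered frames of atomic coordinates (Å), optional velocities (Å/fs)."""

    elements: list[str]
    coordinates: np.ndarray  # (n_frames, n_atoms, 3), Å
    dt: float  # fs
    velocities: np.ndarray | None = None  # (n_frames, n_atoms, 3), Å/fs
    comments: list[str] | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError(
                f"coordinates must be (n_frames, n_atoms, 3), got {self.coordinates.shape}"
            )
        if self.coordinates.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if len(self.elements) != self.coordinates.shape[1]:
            raise ValueError(
                f"{len(self.elements)} element symbols for "
                f"{self.coordinates.shape[1]} atoms"
            )
        if not self.dt > 0:
            raise ValueError(f"timestep must be positive, got {self.dt}")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.coordinates.shape:
                raise ValueError(
                    f"velocities shape {self.velocities.shape} != "
                    f"coordinates shape {self.coordinates.shape}"
                )

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def has_velocities(self) -> bool:
        return self.velocities is not None

    def select_atoms(self, indices: Sequence[int]) -> "Trajectory":
        """Sub-trajectory restricted to the given atom indices (0-based, ordered)."""
        idx = list(indices)
        if len(idx) == 0:
            raise ValueError("empty atom selection")
        if min(idx) < 0 or max(idx) >= self.n_atoms:
            raise IndexError(f"atom index out of range 0..{self.n_atoms - 1}: {idx}")
        return replace(
            self,
            elements=[self.elements[i] for i in idx],
            coordinates=self.coordinates[:, idx, :],
            velocities=None if self.velocities is None else self.velocities[:, idx, :],
        )


@dataclass
class MassWeightedVelocitySeries:
    """Per-frame 3N vector of √mass-scaled velocities, units √amu·Å/fs."""

    times: np.ndarray  # (n_frames,), fs
    values: np.ndarray  # (n_frames, 3N)
    atom_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 2:
            raise ValueError("times must be 1-D and values 2-D")
        if len(self.times) != self.values.shape[0]:
            raise ValueError("times and values disagree on frame count")
        if len(self.times) >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
                raise ValueError("times must be uniformly spaced")
        if self.atom_order and self.values.shape[1] != 3 * len(self.atom_order):
            raise ValueError(
                f"values have {self.values.shape[1]} components, expected "
                f"3 × {len(self.atom_order)} from atom_order"
            )

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def dt(self) -> float:
        if len(self.times) < 2:
            raise ValueError("dt undefined for a single-frame series")
        return float(self.times[1] - self.times[0])


def _parse_properties(comment: str) -> bool | None:
    """Return True/False if the Properties tag states velocity presence, else None."""
    m = _PROPERTIES_RE.search(comment)
    if not m:
        return None
    return ":vel:" in m.group(1).lower()


def read_xyz_trajectory(
    path: str | Path,
    dt: float,
    mass_table: MassTable | None = None,
) -> Trajectory:
    """Read a multi-frame (extended) XYZ file.

    Velocities are populated when per-atom velocity columns are present (either
    declared in a Properties tag or given as plain columns 5–7), otherwise absent.
    Element symbols are validated against ``mass_table`` (standard weights by
    default) so that a downstream mass lookup cannot fail late.
    """
    table = mass_table or MassTable.standard()
    lines = Path(path).read_text().splitlines()
    pos = 0
    frames_xyz: list[np.ndarray] = []
    frames_vel: list[np.ndarray] = []
    comments: list[str] = []
    elements: list[str] | None = None
    has_vel: bool | None = None
    frame = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            natoms = int(lines[pos].strip())
        except ValueError:
            raise TrajectoryFormatError(
                f"{path}: frame {frame}: expected atom count, got {lines[pos]!r}"
            ) from None
        if pos + 1 + natoms >= len(lines) + 1 and pos + 2 + natoms > len(lines):
            raise TrajectoryFormatError(
                f"{path}: frame {frame}: truncated (need {natoms} atom lines)"
            )
        comment = lines[pos + 1]
        declared_vel = _parse_properties(comment)
        syms: list[str] = []
        xyz = np.empty((natoms, 3))
        vel = np.empty((natoms, 3))
        frame_has_vel: bool | None = None
        for a in range(natoms):
            tokens = lines[pos + 2 + a].split()
            if len(tokens) not in (4, 7):
                raise TrajectoryFormatError(
                    f"{path}: frame {frame}, atom {a}: expected 4 or 7 columns, "
                    f"got {len(tokens)}"
                )
            this_vel = len(tokens) == 7
            if declared_vel is True and not this_vel:
                raise TrajectoryFormatError(
                    f"{path}: frame {frame}, atom {a}: Properties declare velocities "
                    "but only 4 columns present"
                )
            if frame_has_vel is None:
                frame_has_vel = this_vel
            elif frame_has_vel != this_vel:
                raise TrajectoryFormatError(
                    f"{path}: frame {frame}: inconsistent column count within frame"
                )
            syms.append(tokens[0])
            try:
                xyz[a] = [float(t) for t in tokens[1:4]]
                if this_vel:
                    vel[a] = [float(t) for t in tokens[4:7]]
            except ValueError:
                raise TrajectoryFormatError(
                    f"{path}: frame {frame}, atom {a}: non-numeric coordinate field"
                ) from None
        if elements is None:
            elements = syms
            for s in elements:
                table.mass_of(s)  # raises UnknownElementError with the symbol
            has_vel = frame_has_vel
        else:
            if len(syms) != len(elements):
                raise TrajectoryFormatError(
                    f"{path}: frame {frame}: atom count {len(syms)} differs from "
                    f"frame 0 ({len(elements)})"
                )
            if syms != elements:
                raise TrajectoryFormatError(
                    f"{path}: frame {frame}: atom ordering differs from frame 0"
                )
            if frame_has_vel != has_vel:
                raise TrajectoryFormatError(
                    f"{path}: frame {frame}: velocity columns "
                    f"{'appeared' if frame_has_vel else 'disappeared'} mid-file"
                )
        frames_xyz.append(xyz)
        if frame_has_vel:
            frames_vel.append(vel)
        comments.append(comment)
        pos += 2 + natoms
        frame += 1
    if elements is None:
        raise TrajectoryFormatError(f"{path}: no frames found")
    # a frame whose atom count line parsed but whose body was shorter would have
    # failed the per-atom column check above, so counts are consistent here
    return Trajectory(
        elements=elements,
        coordinates=np.stack(frames_xyz),
        dt=dt,
        velocities=np.stack(frames_vel) if has_vel else None,
        comments=comments,
    )


def write_xyz_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a Trajectory as multi-frame extended XYZ.

    Numeric fields use 17 significant digits so a write→read round trip
    reproduces the double-precision values exactly.
    """
    props = "species:S:1:pos:R:3" + (":vel:R:3" if traj.has_velocities else "")
    out: list[str] = []
    for f in range(traj.n_frames):
        out.append(str(traj.n_atoms))
        out.append(f"Properties={props} dt={traj.dt:.9g} frame={f}")
        for a in range(traj.n_atoms):
            fields = [f"{traj.elements[a]:<3s}"]
            fields += [f"{v:.16e}" for v in traj.coordinates[f, a]]
            if traj.has_velocities:
                fields += [f"{v:.16e}" for v in traj.velocities[f, a]]
            out.append(" ".join(fields))
    Path(path).write_text("\n".join(out) + "\n")


def estimate_velocities(traj: Trajectory) -> Trajectory:
    """Central-difference velocities for a position-only trajectory.

    v(t_k) = (x(t_{k+1}) − x(t_{k−1})) / (2 dt) on interior frames; the first and
    last frames are dropped so every remaining frame has the same accuracy order.
    """
    if traj.has_velocities:
        raise ValueError("trajectory already carries velocities")
    if traj.n_frames < 3:
        raise InsufficientDataError(
            f"central differences need ≥ 3 frames, got {traj.n_frames}"
        )
    x = traj.coordinates
    v = (x[2:] - x[:-2]) / (2.0 * traj.dt)
    return Trajectory(
        elements=list(traj.elements),
        coordinates=x[1:-1].copy(),
        dt=traj.dt,
        velocities=v,
        comments=None if traj.comments is None else traj.comments[1:-1],
    )


def mass_weight(
    traj: Trajectory,
    masses: MassTable | None = None,
    remove_com_translation: bool = False,
) -> MassWeightedVelocitySeries:
    """Mass-weighted velocity series q̇ with q̇_{3a+k} = √m_a · v_{a,k}.

    With ``remove_com_translation`` the mass-weighted centre-of-mass velocity is
    subtracted from every atom per frame before weighting, which zeroes the three
    global translation components of q̇.
    """
    if not traj.has_velocities:
        raise ValueError(
            "trajectory has no velocities; run estimate_velocities first"
        )
    table = masses or MassTable.standard()
    m = table.masses_for(traj.elements)  # (N,)
    v = traj.velocities
    if remove_com_translation:
        vcom = np.einsum("a,fak->fk", m, v) / m.sum()  # (F, 3)
        v = v - vcom[:, None, :]
    qdot = (v * np.sqrt(m)[None, :, None]).reshape(traj.n_frames, 3 * traj.n_atoms)
    times = np.arange(traj.n_frames) * traj.dt
    return MassWeightedVelocitySeries(
        times=times, values=qdot, atom_order=list(traj.elements)
    )


def parse_atom_selection(spec: str, n_atoms: int) -> list[int]:
    """Parse a 1-based atom selection like ``"1-3,7"`` into 0-based indices."""
    spec = spec.strip()
    if spec.lower().startswith("atoms"):
        spec = spec[5:].strip()
    indices: list[int] = []
    for part in spec.split(","):
        part = part.strip()
        if not part:
            continue
        if "-" in part:
            lo, hi = part.split("-", 1)
            indices.extend(range(int(lo) - 1, int(hi)))
        else:
            indices.append(int(part) - 1)
    if not indices:
        raise ValueError(f"empty atom selection {spec!r}")
    for i in indices:
        if i < 0 or i >= n_atoms:
            raise ValueError(f"atom index {i + 1} outside 1..{n_atoms}")
    return indices
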