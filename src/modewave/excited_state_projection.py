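"""Projection of excited-state trajectory ensembles onto ground-state modes.

A photorelaxation is simulated by an ensemble of excited-state trajectories whose
starting configurations and momenta sample the ground-state equilibrium. As long
as the relaxation stays near the Franck–Condon region, the ground-state mode
composition L still applies, so excited-state mode velocities follow from the
same transformation, Q̇_ES(t) = Lᵀ q̇_ES(t), with t = 0 at each member's first
frame (the excitation instant).

Ensemble averaging is done on wavelet power maps by default (see
``wavelet_transform.average_power``): members have uncorrelated vibrational
phases, so averaging raw velocities destructively cancels the oscillations the
analysis is after. Velocity-domain averaging is available explicitly via
:func:`average_mode_velocities`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DimensionMismatchError
from .generalized_modes import ModeSet, ModeVelocitySeries
from .trajectory_io import MassTable, Trajectory, mass_weight, read_xyz_trajectory

__all__ = [
    "EnsembleSpec",
    "project_ensemble",
    "truncate_common_window",
    "average_mode_velocities",
]


@dataclass
class EnsembleSpec:
    """One or more excited-state trajectories sharing dt and atom ordering.

    ``members`` may be file paths (read lazily with ``dt``) or in-memory
    Trajectory objects.
    """

    members: list  # list[str | Path | Trajectory]
    dt: float
    atom_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValueError("ensemble must have at least one member")

    def load_member(self, i: int, mass_table: MassTable | None = None) -> Trajectory:
        m = self.members[i]
        if isinstance(m, Trajectory):
            return m
        return read_xyz_trajectory(m, self.dt, mass_table)


def _check_atom_order(member_elements: list[str], reference: list[str], label: str) -> None:
    if len(member_elements) != len(reference):
        raise DimensionMismatchError(
            f"{label}: has {len(member_elements)} atoms, modes expect {len(reference)}"
        )
    for i, (a, b) in enumerate(zip(member_elements, reference)):
        if a != b:
            raise DimensionMismatchError(
                f"{label}: atom order mismatch at index {i}: {a!r} != {b!r}"
            )


def project_ensemble(
    ensemble: EnsembleSpec,
    modes: ModeSet,
    masses: MassTable | None = None,
    remove_com_translation: bool = False,
) -> list[ModeVelocitySeries]:
    """Q̇_ES(t) = Lᵀ q̇_ES(t) for every ensemble member.

    Each member is validated against the mode set's atom ordering; its time axis
    is zeroed at its own first frame. Members without stored velocities are
    rejected — estimate them upstream where the frame bookkeeping is explicit.
    """
    out: list[ModeVelocitySeries] = []
    for i in range(len(ensemble.members)):
        traj = ensemble.load_member(i, masses)
        label = (
            traj if isinstance(ensemble.members[i], Trajectory) else ensemble.members[i]
        )
        name = f"member {i}" if isinstance(label, Trajectory) else str(label)
        if modes.atom_order:
            _check_atom_order(traj.elements, modes.atom_order, name)
        series = mass_weight(traj, masses, remove_com_translation)
        if series.values.shape[1] != modes.L.shape[0]:
            raise DimensionMismatchError(
                f"{name}: 3N = {series.values.shape[1]} but modes expect "
                f"{modes.L.shape[0]}"
            )
        out.append(
            ModeVelocitySeries(
                times=series.times - series.times[0],
                values=series.values @ modes.L,
                trajectory_id=name,
            )
        )
    return out


def truncate_common_window(series_list: list[ModeVelocitySeries]) -> list[ModeVelocitySeries]:
    """Truncate all members to the shortest member's frame count."""
    if not series_list:
        raise ValueError("empty series list")
    n = min(s.n_frames for s in series_list)
    return [
        ModeVelocitySeries(
            times=s.times[:n],
            values=s.values[:n],
            mode_ids=s.mode_ids,
            trajectory_id=s.trajectory_id,
        )
        for s in series_list
    ]


def average_mode_velocities(series_list: list[ModeVelocitySeries]) -> ModeVelocitySeries:
    """Elementwise mean of mode velocities across members (phase-sensitive).

    This is the velocity-domain averaging order; with uncorrelated member phases
    it cancels oscillatory content, so power-map averaging is normally
    preferable. Members must share their time axis (truncate first).
    """
    series_list = truncate_common_window(series_list)
    ref = series_list[0]
    for s in series_list[1:]:
        if not np.array_equal(s.mode_ids, ref.mode_ids):
            raise ValueError("members disagree on mode ids")
    return ModeVelocitySeries(
        times=ref.times,
        values=np.mean([s.values for s in series_list], axis=0),
        mode_ids=ref.mode_ids,
        trajectory_id="ensemble-mean",
    )
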