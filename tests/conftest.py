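"""Shared fixtures: reference chain analysis, tiny trajectories, hypothesis profile."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from modewave import (
    assign_frequencies,
    compute_covariance,
    diagonalize,
    mass_weight,
    project,
)
from modewave.synthetic_data import (
    analytic_normal_modes,
    default_chain,
    sample_harmonic_trajectory,
)
from modewave.trajectory_io import Trajectory

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@dataclasses.dataclass
class ChainAnalysis:
    """Everything the reference-chain tests need, computed once per session."""

    model: object
    analytic_freqs: np.ndarray  # cm^-1, ascending
    analytic_vecs: np.ndarray  # (n, n) 1-D mode vectors
    series: object  # MassWeightedVelocitySeries
    covariance: object
    modes: object  # ModeSet with frequencies
    qdot: object  # ModeVelocitySeries


@pytest.fixture(scope="session")
def chain() -> ChainAnalysis:
    """Thermal 5-atom chain, 2^15 frames at dt = 0.5 fs, fully analysed."""
    model = default_chain(temperature=300.0, dt=0.5, n_frames=2**15, seed=7)
    freqs, vecs = analytic_normal_modes(model)
    traj = sample_harmonic_trajectory(model)
    series = mass_weight(traj)
    cov = compute_covariance(series)
    modes = assign_frequencies(diagonalize(cov), series)
    return ChainAnalysis(
        model=model,
        analytic_freqs=freqs,
        analytic_vecs=vecs,
        series=series,
        covariance=cov,
        modes=modes,
        qdot=project(series, modes),
    )


@pytest.fixture
def small_traj() -> Trajectory:
    """Random 5-atom, 10-frame trajectory with velocities."""
    rng = np.random.default_rng(42)
    return Trajectory(
        elements=["H", "C", "O", "N", "H"],
        coordinates=rng.normal(scale=3.0, size=(10, 5, 3)),
        velocities=rng.normal(scale=0.01, size=(10, 5, 3)),
        dt=0.5,
    )
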