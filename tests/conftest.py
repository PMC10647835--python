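"""Shared fixtures: the benchmark bead, optics, and reusable trajectories."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from tirmsim import (
    Environment,
    MobilityModel,
    OpticalModel,
    PotentialModel,
    SimulationConfig,
    simulate_trajectory,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def env() -> Environment:
    return Environment()


@pytest.fixture(scope="session")
def particle3() -> PotentialModel:
    # benchmark bead: B = 1167 kT, kappa^-1 = 10.2 nm, F_g = 64 fN
    return PotentialModel.from_debye_length(1167.0, 10.2, 64.0)


@pytest.fixture(scope="session")
def optics() -> OpticalModel:
    return OpticalModel()  # I0 = 1595 kHz, penetration depth 200.4 nm


@pytest.fixture(scope="session")
def stick_mobility(env) -> MobilityModel:
    return MobilityModel("stick", env)


@pytest.fixture(scope="session")
def traj_p3(particle3, stick_mobility):
    """Full-length noise-free stick trajectory at 2 ms (shared, read-only)."""
    cfg = SimulationConfig(
        n_points=1_000_000, sampling_time=2.0, potential=particle3,
        mobility=stick_mobility, seed=11,
    )
    return simulate_trajectory(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
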