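"""Run configuration: one serializable object that pins down an experiment.

A stored config plus its master seed reproduces every output byte-for-byte.
The YAML layout is flat sections per concern (environment, potential,
optics, simulation, noise, analysis); any omitted key falls back to the
package default, which describes the reference experiment: a 3 um
polystyrene sphere (particle no. 3 parameter set) in water at 293 K,
10^6 samples at 2 ms, I0 = 1595 kHz, penetration depth 200.4 nm.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .detect import OpticalModel
from .physics import Environment, MobilityModel, PotentialModel, SlipCoefficients
from .simulate import SimulationConfig, default_start_grid

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # environment
    temperature: float = 293.0
    viscosity: float = 1.002e-3
    particle_radius_um: float = 3.0
    particle_density: float = 1050.0
    solvent_density: float = 1000.0
    # potential (instrument units: kT, nm, fN)
    amplitude_kT: float = 1167.0
    debye_length_nm: float = 10.2
    gravitational_force_fN: float = 64.0
    # mobility
    mobility: str = "stick"  # 'stick' | 'partial_slip'
    slip_parameter: float = 1.0 / 12.0
    # optics
    intensity_at_contact_kHz: float = 1595.0
    penetration_depth_nm: float = 200.4
    # simulation
    n_points: int = 1_000_000
    sampling_time_ms: float = 2.0
    start_grid_low_nm: float = 1.0
    start_grid_high_nm: float = 800.0
    start_grid_n: int = 1599
    # noise
    shot_noise: bool = True
    background_fraction: float = 0.05
    # analysis
    bin_width_kHz: float = 1.0
    min_count: int = 20
    dynamics_bin_width_nm: float = 15.0
    n_lags: int = 4
    min_occupancy: int = 1000
    subtract_background: bool = True
    # orchestration
    seed: int = 0
    replicates: int = 5

    # ------------------------------------------------------------------
    def environment(self) -> Environment:
        return Environment(
            temperature=self.temperature,
            viscosity=self.viscosity,
            particle_radius=self.particle_radius_um * 1e-6,
            particle_density=self.particle_density,
            solvent_density=self.solvent_density,
        )

    def potential(self) -> PotentialModel:
        return PotentialModel.from_debye_length(
            self.amplitude_kT, self.debye_length_nm, self.gravitational_force_fN
        )

    def optics(self) -> OpticalModel:
        return OpticalModel(self.intensity_at_contact_kHz, self.penetration_depth_nm)

    def mobility_model(self) -> MobilityModel:
        env = self.environment()
        if self.mobility == "stick":
            return MobilityModel("stick", env)
        return MobilityModel(
            "partial_slip", env, SlipCoefficients.from_slip_parameter(self.slip_parameter)
        )

    def simulation(self, seed: int | None = None) -> SimulationConfig:
        return SimulationConfig(
            n_points=self.n_points,
            sampling_time=self.sampling_time_ms,
            potential=self.potential(),
            mobility=self.mobility_model(),
            env=self.environment(),
            seed=self.seed if seed is None else seed,
            start_grid=default_start_grid(
                self.start_grid_low_nm, self.start_grid_high_nm, self.start_grid_n
            ),
        )

    # ------------------------------------------------------------------
    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
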