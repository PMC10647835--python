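"""Reference parameter sets for a 3 um polystyrene sphere in 1 mM NaCl.

``REFERENCE_PARTICLES`` holds wall-potential parameters (B in k_BT, kappa in
1/nm, F_g in fN) measured for six individual beads of the same nominal
sample; bead-to-bead scatter in the electrostatic amplitude spans almost two
orders of magnitude while the gravitational force varies by ~10%.  Particle
no. 3 is the canonical benchmark system used throughout the examples and
tests: B = 1167 k_BT, kappa^-1 = 10.2 nm, F_g = 64 fN, which puts the
potential minimum near 91 nm.
"""

from __future__ import annotations

from .detect import OpticalModel
from .physics import Environment, PotentialModel

__all__ = [
    "REFERENCE_PARTICLES",
    "PARTICLE_3",
    "DEFAULT_ENV",
    "DEFAULT_OPTICS_PRESET",
]

#: Fitted potential parameters for six beads, keyed by particle number.
REFERENCE_PARTICLES: dict[int, PotentialModel] = {
    1: PotentialModel.from_debye_length(655.0, 12.41, 57.0),
    2: PotentialModel.from_debye_length(115.0, 10.4, 61.0),
    3: PotentialModel.from_debye_length(1167.0, 10.2, 64.0),
    4: PotentialModel.from_debye_length(165.0, 9.7, 57.0),
    5: PotentialModel.from_debye_length(8780.0, 11.3, 54.0),
    6: PotentialModel.from_debye_length(1555.0, 9.1, 52.0),
}

#: The benchmark bead used in the worked examples.
PARTICLE_3 = REFERENCE_PARTICLES[3]

#: Water at 293 K, 3 um polystyrene sphere.
DEFAULT_ENV = Environment()

#: Calibrated evanescent-field coupling: I0 = 1595 kHz, depth 200.4 nm.
DEFAULT_OPTICS_PRESET = OpticalModel()
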