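"""Closed-form physics of a colloidal sphere near a flat wall.

This module collects everything that can be written down analytically for a
micron-sized sphere interacting with a wall across an electrolyte solution:

* the DLVO-type wall potential — screened electrostatic repulsion plus the
  gravitational pseudo-attraction of a settling sphere,
* hindered normal diffusion under stick boundary conditions (Brenner wall
  drag) and under partial slip (lubrication expansion with tabulated
  coefficients),
* the drift velocity of an overdamped particle in that potential, including
  the spurious-drift contribution of the position-dependent mobility,
* experiment-design helpers: position of the potential minimum, Debye length
  from salt concentration, buoyant weight, and the maximum admissible
  sampling time before the constant-force assumption breaks down.

Unit convention
---------------
Internally everything is SI.  The user-facing surface speaks the units the
instrument community uses: separations in nm, energies in units of k_BT,
forces in fN, inverse screening lengths in 1/nm.  Conversions happen at the
function boundary, never inside a formula.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.constants import Boltzmann as _K_B

NM = 1e-9  # m per nm
FN = 1e-15  # N per fN

__all__ = [
    "Environment",
    "PotentialModel",
    "SlipCoefficients",
    "MobilityModel",
    "DEFAULT_ENVIRONMENT",
    "SLIP_TABLE",
    "potential_energy",
    "wall_force",
    "minimum_position",
    "amplitude_from_minimum",
    "hmin_over_href",
    "debye_length_from_salt",
    "buoyant_weight",
    "diffusion_stick",
    "diffusion_stick_derivative",
    "stick_mobility_ratio",
    "diffusion_slip",
    "diffusion_slip_derivative",
    "slip_length",
    "drift_velocity_theory",
    "max_sampling_time",
]


@dataclass(frozen=True)
class Environment:
    """Solvent, particle and thermodynamic state (SI units).

    Defaults describe the reference system: a 3 um polystyrene sphere in
    water at 293 K.
    """

    temperature: float = 293.0  # K
    viscosity: float = 1.002e-3  # Pa s, water at 293 K
    particle_radius: float = 3.0e-6  # m
    particle_density: float = 1050.0  # kg/m^3, polystyrene
    solvent_density: float = 1000.0  # kg/m^3
    gravity: float = 9.81  # m/s^2

    def __post_init__(self) -> None:
        for name in (
            "temperature",
            "viscosity",
            "particle_radius",
            "particle_density",
            "solvent_density",
            "gravity",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.particle_density <= self.solvent_density:
            raise ValueError(
                "particle_density must exceed solvent_density "
                "(the sphere must settle toward the wall)"
            )

    @property
    def kT(self) -> float:
        """Thermal energy k_B*T in J."""
        return _K_B * self.temperature

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/(k_B*T) in 1/J."""
        return 1.0 / self.kT

    @property
    def stokes_drag(self) -> float:
        """Bulk Stokes friction coefficient 6*pi*eta*R in kg/s."""
        return 6.0 * np.pi * self.viscosity * self.particle_radius

    @property
    def bulk_diffusion(self) -> float:
        """Stokes-Einstein bulk diffusion coefficient D0 in m^2/s."""
        return self.kT / self.stokes_drag


DEFAULT_ENVIRONMENT = Environment()


@dataclass(frozen=True)
class PotentialModel:
    """Wall potential phi(h) = B exp(-kappa h) + F_g h.

    Parameters are carried in the units in which they are usually quoted:
    ``amplitude`` B in k_BT, ``kappa`` in 1/nm, ``gravitational_force`` F_g
    in fN.  The exponential term is the screened double-layer repulsion; the
    linear term is the buoyancy-corrected weight pressing the sphere toward
    the wall.
    """

    amplitude: float  # B, k_BT
    kappa: float  # inverse Debye length, 1/nm
    gravitational_force: float  # F_g, fN

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude B must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.gravitational_force <= 0:
            raise ValueError("gravitational_force must be > 0")

    @classmethod
    def from_debye_length(
        cls, amplitude: float, debye_length_nm: float, gravitational_force: float
    ) -> "PotentialModel":
        return cls(amplitude, 1.0 / debye_length_nm, gravitational_force)

    @property
    def debye_length(self) -> float:
        """Debye screening length kappa^-1 in nm."""
        return 1.0 / self.kappa


@dataclass(frozen=True)
class SlipCoefficients:
    """Lubrication coefficients for partial-slip normal friction.

    The friction bracket A/eps - B ln(eps) + C - D eps ln(eps), with
    eps = h/R, approximates the near-wall normal friction (in units of the
    Stokes coefficient 6 pi eta R) for a given slip parameter zeta.  The
    coefficient values originate from high-accuracy multipole computations
    and are shipped as constants; A = 1/4 for every tabulated zeta.
    """

    zeta: float
    A: float
    B: float
    C: float
    D: float

    @classmethod
    def from_slip_parameter(cls, zeta: float) -> "SlipCoefficients":
        """Look up the built-in coefficient table by slip parameter."""
        for row in SLIP_TABLE:
            if np.isclose(zeta, row.zeta, rtol=1e-9, atol=1e-12):
                return row
        known = ", ".join(f"{r.zeta:.6g}" for r in SLIP_TABLE)
        raise KeyError(f"no tabulated coefficients for zeta={zeta}; known: {known}")


#: Tabulated lubrication coefficients, keyed by slip parameter zeta.
SLIP_TABLE: tuple[SlipCoefficients, ...] = (
    SlipCoefficients(zeta=1.0 / 12.0, A=0.25, B=3.5749, C=-6.2238, D=10.7),
    SlipCoefficients(zeta=0.12, A=0.25, B=2.20, C=-2.6414, D=4.55),
    SlipCoefficients(zeta=1.0 / 3.0, A=0.25, B=0.2, C=0.708214, D=0.033),
)

#: Above this eps = h/R the lubrication expansion is no longer trustworthy.
LUBRICATION_EPS_CUTOFF = 0.3


def potential_energy(h, model: PotentialModel, env: Environment = DEFAULT_ENVIRONMENT):
    """Wall potential phi(h) in k_BT at surface separation ``h`` (nm)."""
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("separation h must be >= 0")
    grav_kT = model.gravitational_force * FN * h * NM / env.kT
    out = model.amplitude * np.exp(-model.kappa * h) + grav_kT
    return out if out.ndim else float(out)


def wall_force(h, model: PotentialModel, env: Environment = DEFAULT_ENVIRONMENT):
    """Force -d(phi)/dh on the particle in N; positive pushes away from the wall."""
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("separation h must be >= 0")
    b_joule = model.amplitude * env.kT
    kappa_m = model.kappa / NM
    out = b_joule * kappa_m * np.exp(-model.kappa * h) - model.gravitational_force * FN
    return out if out.ndim else float(out)


def minimum_position(model: PotentialModel, env: Environment = DEFAULT_ENVIRONMENT) -> float:
    """Position h_min = (1/kappa) ln(kappa B / F_g) of the potential minimum, nm.

    Raises ``ValueError`` when kappa*B <= F_g, i.e. the repulsion is too weak
    to balance gravity anywhere and the potential has no minimum at h > 0.
    """
    ratio = _kappa_b_over_fg(model, env)
    if ratio <= 1.0:
        raise ValueError("kappa*B <= F_g: potential has no minimum (particle sticks)")
    return np.log(ratio) / model.kappa


def amplitude_from_minimum(
    gravitational_force: float,
    kappa: float,
    h_min: float,
    env: Environment = DEFAULT_ENVIRONMENT,
) -> float:
    """Electrostatic amplitude B = (F_g/kappa) exp(kappa h_min), in k_BT.

    Inverts the minimum condition; ``gravitational_force`` in fN, ``kappa``
    in 1/nm, ``h_min`` in nm.
    """
    b_joule = (gravitational_force * FN) / (kappa / NM) * np.exp(kappa * h_min)
    return b_joule / env.kT


def hmin_over_href(
    model: PotentialModel,
    penetration_constant: float,
    env: Environment = DEFAULT_ENVIRONMENT,
) -> float:
    """Ratio h_min/h_ref between the potential minimum and the most-frequent-
    intensity separation.

    ``penetration_constant`` is the evanescent decay constant Lambda in 1/nm.
    h_ref exceeds h_min because the intensity histogram maximum corresponds
    to the maximum of p(h)*I(h)'s Jacobian-weighted density, displaced
    outward by the photon-side weighting Lambda*k_BT.
    """
    ratio = _kappa_b_over_fg(model, env)
    if ratio <= 1.0:
        raise ValueError("kappa*B <= F_g: potential has no minimum")
    lam_force = penetration_constant / NM * env.kT  # Lambda * kT, units N
    fg = model.gravitational_force * FN
    if fg <= lam_force:
        raise ValueError(
            "F_g <= Lambda*k_BT: histogram reference separation is undefined"
        )
    b_joule = model.amplitude * env.kT
    kappa_m = model.kappa / NM
    return float(np.log(ratio) / np.log(kappa_m * b_joule / (fg - lam_force)))


def _kappa_b_over_fg(model: PotentialModel, env: Environment) -> float:
    b_joule = model.amplitude * env.kT
    return (model.kappa / NM) * b_joule / (model.gravitational_force * FN)


def debye_length_from_salt(concentration_molar: float) -> float:
    """Debye length in nm for a 1:1 electrolyte at molar concentration c_s.

    Uses the room-temperature aqueous estimate kappa^-1 [nm] = 0.304/sqrt(c_s [M]).
    """
    if concentration_molar <= 0:
        raise ValueError("salt concentration must be > 0")
    return 0.304 / np.sqrt(concentration_molar)


def buoyant_weight(env: Environment = DEFAULT_ENVIRONMENT) -> tuple[float, float]:
    """Buoyancy-corrected mass (kg) and weight (fN) of the sphere."""
    mass = (
        4.0 / 3.0 * np.pi * env.particle_radius**3
        * (env.particle_density - env.solvent_density)
    )
    return mass, mass * env.gravity / FN


# ---------------------------------------------------------------------------
# Hindered normal diffusion
# ---------------------------------------------------------------------------

def stick_mobility_ratio(h, env: Environment = DEFAULT_ENVIRONMENT):
    """lambda^-1(h) = D_n(h)/D0 for stick boundary conditions.

    Pade-type approximation to the exact series solution for the normal
    mobility of a sphere near a plane wall:
    lambda^-1 = (6h^2 + 2hR) / (6h^2 + 9hR + 2R^2).
    """
    h_m = np.asarray(h, dtype=float) * NM
    if np.any(h_m < 0):
        raise ValueError("separation h must be >= 0")
    r = env.particle_radius
    out = (6 * h_m**2 + 2 * h_m * r) / (6 * h_m**2 + 9 * h_m * r + 2 * r**2)
    return out if out.ndim else float(out)


def diffusion_stick(h, env: Environment = DEFAULT_ENVIRONMENT):
    """Normal diffusion coefficient D_n(h) (m^2/s), stick boundary conditions.

    ``h`` is the surface separation in nm.  D_n rises monotonically from 0 at
    contact to the bulk value D0 far from the wall.
    """
    out = env.bulk_diffusion * np.asarray(stick_mobility_ratio(h, env))
    return out if out.ndim else float(out)


def diffusion_stick_derivative(h, env: Environment = DEFAULT_ENVIRONMENT):
    """Analytic derivative dD_n/dz of the stick mobility, (m^2/s)/m.

    z = h + R, but for a rigid wall dD/dz = dD/dh.
    """
    h_m = np.asarray(h, dtype=float) * NM
    if np.any(h_m < 0):
        raise ValueError("separation h must be >= 0")
    r = env.particle_radius
    num = 6 * h_m**2 + 2 * h_m * r
    den = 6 * h_m**2 + 9 * h_m * r + 2 * r**2
    dnum = 12 * h_m + 2 * r
    dden = 12 * h_m + 9 * r
    out = env.bulk_diffusion * (dnum * den - num * dden) / den**2
    return out if out.ndim else float(out)


def _slip_bracket(eps, slip: SlipCoefficients):
    return slip.A / eps - slip.B * np.log(eps) + slip.C - slip.D * eps * np.log(eps)


def diffusion_slip(
    h,
    env: Environment = DEFAULT_ENVIRONMENT,
    slip: SlipCoefficients | None = None,
    eps_cutoff: float = LUBRICATION_EPS_CUTOFF,
):
    """Normal diffusion coefficient (m^2/s) under partial slip.

    Lubrication expansion D_n = D0 / (A/eps - B ln eps + C - D eps ln eps)
    with eps = h/R; the friction bracket is expressed in units of the Stokes
    coefficient 6 pi eta R.  Valid for small eps; a warning is issued above
    ``eps_cutoff``.
    """
    if slip is None:
        raise ValueError("partial-slip diffusion requires SlipCoefficients")
    eps = np.asarray(h, dtype=float) / (env.particle_radius / NM)
    if np.any(eps <= 0):
        raise ValueError("partial-slip mobility requires h > 0")
    if np.any(eps > eps_cutoff):
        warnings.warn(
            f"eps = h/R exceeds {eps_cutoff}: outside the lubrication regime",
            stacklevel=2,
        )
    bracket = _slip_bracket(eps, slip)
    if np.any(bracket <= 0):
        raise ValueError("non-positive friction bracket: outside model validity")
    out = env.bulk_diffusion / bracket
    return out if out.ndim else float(out)


def diffusion_slip_derivative(
    h,
    env: Environment = DEFAULT_ENVIRONMENT,
    slip: SlipCoefficients | None = None,
):
    """Analytic derivative dD_n/dz of the partial-slip mobility, (m^2/s)/m."""
    if slip is None:
        raise ValueError("partial-slip diffusion requires SlipCoefficients")
    r_nm = env.particle_radius / NM
    eps = np.asarray(h, dtype=float) / r_nm
    if np.any(eps <= 0):
        raise ValueError("partial-slip mobility requires h > 0")
    bracket = _slip_bracket(eps, slip)
    dbracket = -slip.A / eps**2 - slip.B / eps - slip.D * (np.log(eps) + 1.0)
    out = -env.bulk_diffusion * dbracket / bracket**2 / env.particle_radius
    return out if out.ndim else float(out)


def slip_length(zeta: float, radius: float) -> float:
    """Slip length l_s = zeta*R/(1 - 3*zeta), same units as ``radius``.

    Diverges at zeta = 1/3 (returned as ``inf``); zeta > 1/3 is rejected.
    """
    if zeta < 0:
        raise ValueError("slip parameter zeta must be >= 0")
    if zeta > 1.0 / 3.0:
        raise ValueError("slip parameter zeta must be <= 1/3")
    if np.isclose(zeta, 1.0 / 3.0):
        return float("inf")
    return zeta * radius / (1.0 - 3.0 * zeta)


@dataclass(frozen=True)
class MobilityModel:
    """Position-dependent normal mobility: stick or partial-slip wall drag."""

    kind: str = "stick"  # 'stick' | 'partial_slip'
    env: Environment = field(default_factory=Environment)
    slip: SlipCoefficients | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("stick", "partial_slip"):
            raise ValueError("kind must be 'stick' or 'partial_slip'")
        if self.kind == "partial_slip" and self.slip is None:
            raise ValueError("partial_slip mobility requires slip coefficients")

    def diffusion(self, h):
        """D_n(h) in m^2/s; h in nm."""
        if self.kind == "stick":
            return diffusion_stick(h, self.env)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return diffusion_slip(h, self.env, self.slip)

    def diffusion_derivative(self, h):
        """dD_n/dz in (m^2/s)/m; h in nm."""
        if self.kind == "stick":
            return diffusion_stick_derivative(h, self.env)
        return diffusion_slip_derivative(h, self.env, self.slip)

    def mobility_ratio(self, h):
        """D_n(h)/D0, dimensionless."""
        return np.asarray(self.diffusion(h)) / self.env.bulk_diffusion


def drift_velocity_theory(
    h,
    model: PotentialModel,
    mobility: MobilityModel,
):
    """Analytic drift velocity v(z) = dD_n/dz - beta D_n dphi/dh, in m/s.

    The first term is the spurious drift of the position-dependent mobility;
    the second is the force-driven drift.  Far from the wall with gravity
    only this reduces to the Stokes settling velocity -F_g/(6 pi eta R).
    """
    env = mobility.env
    d = np.asarray(mobility.diffusion(h))
    dd = np.asarray(mobility.diffusion_derivative(h))
    # wall_force returns -dphi/dh, so the force term is +beta*D*wall_force
    out = dd + env.beta * d * np.asarray(wall_force(h, model, env))
    return out if out.ndim else float(out)


def max_sampling_time(
    h,
    model: PotentialModel,
    env: Environment = DEFAULT_ENVIRONMENT,
    dh: float = 0.2,
):
    """Maximum admissible sampling time Delta_t_max in ms at separation h (nm).

    Rule of thumb for experiment design: the force-driven drift must not move
    the particle by more than the height resolution ``dh`` (nm) within one
    sampling interval, otherwise the constant-force assumption that underlies
    both the Boltzmann inversion and the simulation step is violated:
    Delta_t_max = dh * 6 pi eta R / (|dphi/dh| * lambda^-1(h)).
    Where the force vanishes (at the potential minimum) the admissible time
    is infinite.
    """
    force = np.abs(np.asarray(wall_force(h, model, env), dtype=float))
    lam_inv = np.asarray(stick_mobility_ratio(h, env))
    with np.errstate(divide="ignore"):
        dt_s = np.where(
            force > 0.0,
            dh * NM * env.stokes_drag / np.where(force > 0, force * lam_inv, 1.0),
            np.inf,
        )
    out = dt_s * 1e3
    return out if out.ndim else float(out)
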