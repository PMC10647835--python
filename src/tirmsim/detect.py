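"""Evanescent-wave optics and photon-detection noise models.

The scattered intensity of a sphere in an evanescent field decays
exponentially with the wall separation, I(h) = I0 exp(-Lambda h), with I0
the count rate at contact and Lambda the inverse penetration depth.  This
module converts between separations and count rates, and corrupts clean
intensity traces with the two noise sources a photon-counting detector
cannot avoid: Poisson shot noise of the photon count within a sampling
interval, and additive Poisson background scattering from everything that
is not the probe particle.

Poisson statistics are applied to integer photon counts per sampling
interval (n = I * Delta_t), not to count-rate values: the photomultiplier
counts photons, and this reproduces the observed count-rate granularity of
1 count per interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OpticalModel",
    "IntensityTrace",
    "DEFAULT_OPTICS",
    "penetration_constant",
    "intensity_from_height",
    "height_from_intensity",
    "apply_shot_noise",
    "apply_background_noise",
]

#: Number of leading samples used to estimate the mean signal level for the
#: background-noise model.
N_TEST_SAMPLES = 10_000


def penetration_constant(n1: float, n2: float, alpha: float, wavelength: float) -> float:
    """Inverse penetration depth Lambda (1/nm) of the evanescent field.

    Lambda = (4 pi / lambda0) sqrt((n1 sin alpha)^2 - n2^2) for total
    internal reflection at a substrate (index ``n1``) / suspension (``n2``)
    interface, incidence angle ``alpha`` in radians, vacuum wavelength in nm.
    """
    s = (n1 * np.sin(alpha)) ** 2 - n2**2
    if s <= 0:
        raise ValueError(
            "incidence angle below the critical angle: no evanescent field"
        )
    return 4.0 * np.pi / wavelength * np.sqrt(s)


@dataclass(frozen=True)
class OpticalModel:
    """Evanescent-field coupling: count rate at contact and penetration depth.

    ``intensity_at_contact`` I0 in kHz; ``penetration_depth`` Lambda^-1 in nm.
    """

    intensity_at_contact: float = 1595.0  # kHz
    penetration_depth: float = 200.4  # nm

    def __post_init__(self) -> None:
        if self.intensity_at_contact <= 0:
            raise ValueError("intensity_at_contact must be > 0")
        if self.penetration_depth <= 0:
            raise ValueError("penetration_depth must be > 0")

    @property
    def decay_constant(self) -> float:
        """Lambda in 1/nm."""
        return 1.0 / self.penetration_depth

    @classmethod
    def from_angles(
        cls,
        intensity_at_contact: float,
        n1: float,
        n2: float,
        alpha: float,
        wavelength: float,
    ) -> "OpticalModel":
        """Build from refractive indices, incidence angle (rad) and vacuum
        wavelength (nm) instead of a calibrated penetration depth."""
        lam = penetration_constant(n1, n2, alpha, wavelength)
        return cls(intensity_at_contact, 1.0 / lam)


DEFAULT_OPTICS = OpticalModel()


@dataclass(frozen=True)
class IntensityTrace:
    """Detected count rates (kHz) at a fixed sampling time (ms)."""

    sampling_time: float
    values: np.ndarray
    optics: OpticalModel = DEFAULT_OPTICS
    noise_flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.sampling_time <= 0:
            raise ValueError("sampling_time must be > 0")
        if np.any(self.values < 0):
            raise ValueError("count rates must be >= 0")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def counts_per_sample(self) -> np.ndarray:
        """Expected (or realized) photon counts per sampling interval."""
        return self.values * 1e3 * self.sampling_time * 1e-3


def intensity_from_height(h, optics: OpticalModel = DEFAULT_OPTICS):
    """Count rate I(h) = I0 exp(-Lambda h) in kHz; ``h`` in nm."""
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("separation h must be >= 0")
    out = optics.intensity_at_contact * np.exp(-optics.decay_constant * h)
    return out if out.ndim else float(out)


def height_from_intensity(intensity, optics: OpticalModel = DEFAULT_OPTICS):
    """Separation h = (1/Lambda) ln(I0/I) in nm; exact inverse of
    :func:`intensity_from_height`.

    Intensities above I0 would map to negative separations and are rejected,
    as are non-positive intensities.
    """
    i = np.asarray(intensity, dtype=float)
    if np.any(i <= 0):
        raise ValueError("intensity must be > 0")
    if np.any(i > optics.intensity_at_contact * (1 + 1e-12)):
        raise ValueError("intensity exceeds the contact value I0 (negative height)")
    out = optics.penetration_depth * np.log(optics.intensity_at_contact / i)
    return out if out.ndim else float(out)


def apply_shot_noise(trace: IntensityTrace, rng: np.random.Generator) -> IntensityTrace:
    """Replace each sample by a Poisson draw of its expected photon count.

    The expected count per interval is n = I * Delta_t; the returned trace
    holds the realized counts converted back to kHz.  The mean is preserved
    and the variance equals the mean in count space, so the relative
    fluctuation is 1/sqrt(n).
    """
    dt_s = trace.sampling_time * 1e-3
    counts = rng.poisson(trace.values * 1e3 * dt_s)
    return IntensityTrace(
        trace.sampling_time,
        counts / (1e3 * dt_s),
        trace.optics,
        trace.noise_flags + ("shot",),
    )


def apply_background_noise(
    trace: IntensityTrace,
    background_fraction: float,
    rng: np.random.Generator,
) -> IntensityTrace:
    """Add Poisson background scattering at a fraction of the signal level.

    The mean signal <I_test> is estimated from the first 10^4 samples (or
    all, if fewer); each sample then receives an independent Poisson count
    with mean ``background_fraction * <I_test> * Delta_t``.  The default
    working point of a well-aligned instrument keeps this fraction below
    0.05.
    """
    if not 0.0 <= background_fraction < 1.0:
        raise ValueError("background_fraction must be in [0, 1)")
    if background_fraction == 0.0:
        return trace
    dt_s = trace.sampling_time * 1e-3
    i_test = float(trace.values[:N_TEST_SAMPLES].mean())
    bg_counts = rng.poisson(background_fraction * i_test * 1e3 * dt_s, size=len(trace))
    return IntensityTrace(
        trace.sampling_time,
        trace.values + bg_counts / (1e3 * dt_s),
        trace.optics,
        trace.noise_flags + ("background",),
    )
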