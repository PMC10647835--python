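"""Interaction-potential reconstruction from an intensity trace.

Workflow: histogram the observed count rates, pick the most frequent
intensity as the reference, Boltzmann-invert the histogram into a potential
difference profile Delta_phi(h), and fit the two-parameter-family wall
potential (screened repulsion + gravity) to the profile.

The inversion uses the fact that the probability of observing an intensity
equals the probability of the corresponding separation:

    p(h)/p(h_ref) = [I(h) N(I(h))] / [I_ref N(I_ref)] = exp(-beta Delta_phi)

The factor I(h) is the Jacobian |dI/dh| = Lambda I(h) of the exponential
intensity-distance coupling (the constant Lambda cancels in the ratio).
Separations come from the bin-center intensities via h = ln(I0/I)/Lambda, so
the x and y coordinates of the profile are obtained independently of each
other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .detect import IntensityTrace, OpticalModel, height_from_intensity
from .physics import (
    DEFAULT_ENVIRONMENT,
    FN,
    NM,
    Environment,
    amplitude_from_minimum,
    debye_length_from_salt,
)

logger = logging.getLogger(__name__)

__all__ = [
    "IntensityHistogram",
    "PotentialProfile",
    "PotentialFit",
    "build_histogram",
    "reference_point",
    "profile_from_histogram",
    "fit_profile",
    "potential_model_curve",
]

DEFAULT_BIN_WIDTH = 1.0  # kHz, the count-rate resolution at 2 ms sampling
DEFAULT_MIN_COUNT = 20  # drop bins rarer than this (~10 kT above the minimum)


@dataclass(frozen=True)
class IntensityHistogram:
    """Uniform-width histogram of observed count rates."""

    bin_edges: np.ndarray  # kHz, length nbins+1
    counts: np.ndarray  # nonnegative integers, length nbins

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, dtype=float))
        object.__setattr__(self, "counts", np.asarray(self.counts))
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("need len(bin_edges) == len(counts) + 1")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class PotentialProfile:
    """Reconstructed potential differences Delta_phi(h), zero at h_ref.

    ``heights`` in nm, ``dphi`` in k_BT, ``sigma`` the per-point counting
    uncertainty (k_BT) propagated from the bin occupancies.
    """

    heights: np.ndarray
    dphi: np.ndarray
    sigma: np.ndarray
    h_ref: float
    counts: np.ndarray
    bin_width: float = DEFAULT_BIN_WIDTH
    min_count: int = DEFAULT_MIN_COUNT


@dataclass(frozen=True)
class PotentialFit:
    """Best-fit wall-potential parameters from a reconstructed profile."""

    gravitational_force: float  # fN
    h_min: float  # nm
    kappa: float  # 1/nm
    amplitude: float  # B in k_BT, via the minimum condition
    offset: float  # k_BT, free additive constant absorbed by the fit
    residual_norm: float
    covariance: np.ndarray = field(repr=False)
    n_points: int = 0

    @property
    def debye_length(self) -> float:
        return 1.0 / self.kappa


def build_histogram(
    trace: IntensityTrace, bin_width: float = DEFAULT_BIN_WIDTH
) -> IntensityHistogram:
    """Histogram the trace with uniform bins of ``bin_width`` kHz.

    Bin edges are aligned to integer multiples of the bin width so that a
    given count rate always falls in the same bin regardless of the trace's
    range; total counts equal the number of samples.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if len(trace) == 0:
        raise ValueError("empty trace")
    v = trace.values
    lo = np.floor(v.min() / bin_width) * bin_width
    hi = np.ceil(v.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = lo + bin_width * np.arange(round((hi - lo) / bin_width) + 1)
    counts, _ = np.histogram(v, bins=edges)
    return IntensityHistogram(edges, counts)


def reference_point(
    hist: IntensityHistogram, optics: OpticalModel
) -> tuple[float, float]:
    """Most frequent intensity I_ref (kHz) and its separation h_ref (nm).

    Ties across bins are resolved toward the lower intensity, i.e. the
    larger separation (with 10^6 samples a tie is measure-zero; it is
    logged when it occurs).
    """
    if hist.total == 0:
        raise ValueError("histogram is empty")
    cmax = hist.counts.max()
    idx = int(np.flatnonzero(hist.counts == cmax)[0])
    if np.count_nonzero(hist.counts == cmax) > 1:
        logger.info("histogram maximum tie; using the lowest-intensity bin")
    i_ref = float(hist.bin_centers[idx])
    return i_ref, float(height_from_intensity(i_ref, optics))


def profile_from_histogram(
    hist: IntensityHistogram,
    optics: OpticalModel,
    min_count: int | None = None,
) -> PotentialProfile:
    """Boltzmann-invert an intensity histogram into Delta_phi(h).

    Only bins with at least ``min_count`` samples contribute; for each such
    bin, the separation comes from the bin-center intensity and

        Delta_phi/k_BT = -ln[(I N(I)) / (I_ref N(I_ref))].

    The per-point counting uncertainty is sqrt(1/N + 1/N_ref) k_BT.

    The default threshold is 20 counts per 10^6 trace samples (scaled
    proportionally for longer or shorter traces), which keeps the working
    range at roughly 10 k_BT above the potential minimum independent of the
    trace length.
    """
    i_ref, h_ref = reference_point(hist, optics)
    n_ref = hist.counts.max()
    if min_count is None:
        min_count = max(DEFAULT_MIN_COUNT, round(DEFAULT_MIN_COUNT * hist.total / 1e6))
    keep = hist.counts >= max(min_count, 1)
    if not np.any(keep):
        raise ValueError("all bins below the count threshold")
    centers = hist.bin_centers[keep]
    counts = hist.counts[keep].astype(float)
    heights = np.asarray(height_from_intensity(centers, optics))
    dphi = -np.log((centers * counts) / (i_ref * n_ref))
    sigma = np.sqrt(1.0 / counts + 1.0 / n_ref)
    order = np.argsort(heights)
    bin_width = float(hist.bin_edges[1] - hist.bin_edges[0])
    return PotentialProfile(
        heights[order],
        dphi[order],
        sigma[order],
        h_ref,
        counts[order].astype(int),
        bin_width,
        min_count,
    )


def compare_profiles(
    a: PotentialProfile,
    b: PotentialProfile,
    window: tuple[float, float] = (55.0, 250.0),
    max_shift: float = 20.0,
) -> tuple[float, float, float]:
    """Shape comparison of two profiles modulo a distance-calibration shift.

    Detector background offsets (and the bin-discrete choice of the
    reference intensity) displace the absolute distance axis of a
    reconstructed profile without altering its shape.  This registers ``b``
    onto ``a`` by the rigid x-shift (within ``+-max_shift`` nm) that
    minimizes the RMS difference over ``window`` (nm, on ``a``'s axis) and
    returns ``(shift_nm, rms_kT, max_abs_kT)`` of the residual shape
    difference.
    """
    sel = (a.heights >= window[0]) & (a.heights <= window[1])
    if not np.any(sel):
        raise ValueError("comparison window contains no profile points")
    ha, ya = a.heights[sel], a.dphi[sel]
    best = (0.0, np.inf, np.inf)
    for shift in np.arange(-max_shift, max_shift + 0.125, 0.25):
        yb = np.interp(ha, b.heights + shift, b.dphi)
        d = ya - yb
        rms = float(np.sqrt(np.mean(d**2)))
        if rms < best[1]:
            best = (float(shift), rms, float(np.max(np.abs(d))))
    return best


def potential_model_curve(h, f_g, h_min, kappa, offset=0.0, env=DEFAULT_ENVIRONMENT):
    """Fit model Delta_phi(h) in k_BT with the amplitude eliminated.

    Using d(phi)/dh = 0 at h_min to eliminate B gives

        Delta_phi = (F_g/kappa)[exp(-kappa(h - h_min)) - 1] + F_g (h - h_min)

    (zero at h_min); ``f_g`` in fN, lengths in nm, plus a free additive
    ``offset`` in k_BT.
    """
    h = np.asarray(h, dtype=float)
    fg_kt_per_nm = f_g * FN * NM / env.kT  # k_BT per nm
    x = h - h_min
    return fg_kt_per_nm / kappa * (np.exp(-kappa * x) - 1.0) + fg_kt_per_nm * x + offset


def fit_profile(
    profile: PotentialProfile,
    env: Environment = DEFAULT_ENVIRONMENT,
    salt_concentration: float = 1e-3,
    weighted: bool = False,
) -> PotentialFit:
    """Nonlinear least-squares fit of the wall potential to a profile.

    Floating parameters are the gravitational force F_g, the minimum
    position h_min and the inverse screening length kappa, plus a free
    additive offset (the profile is pinned to zero at h_ref by construction,
    but bin discretization makes a free offset numerically safer).  The
    electrostatic amplitude B is recovered afterwards from the minimum
    condition B = (F_g/kappa) exp(kappa h_min).

    Initialization: F_g from the slope of the outer 30% of the profile
    (pure-gravity tail), h_min from the profile argmin, kappa from the
    nominal ``salt_concentration`` (mol/L).  The fit is unweighted by
    default; ``weighted=True`` uses the per-point counting uncertainties.
    """
    h = profile.heights
    y = profile.dphi
    if len(h) < 5:
        raise ValueError("profile too short to fit (need >= 5 points)")
    # initial guesses
    n_tail = max(3, int(0.3 * len(h)))
    tail = slice(len(h) - n_tail, len(h))
    slope_kt_nm = max(np.polyfit(h[tail], y[tail], 1)[0], 1e-8)
    fg0 = slope_kt_nm * env.kT / NM / FN  # fN
    hmin0 = float(h[np.argmin(y)])
    kappa0 = 1.0 / debye_length_from_salt(salt_concentration)

    def model(hh, f_g, h_min, kappa, offset):
        return potential_model_curve(hh, f_g, h_min, kappa, offset, env)

    sigma = profile.sigma if weighted else None
    popt, pcov = curve_fit(
        model,
        h,
        y,
        p0=[fg0, hmin0, kappa0, 0.0],
        sigma=sigma,
        bounds=([0.0, 0.0, 1e-4, -np.inf], [np.inf, np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    f_g, h_min, kappa, offset = (float(p) for p in popt)
    resid = y - model(h, *popt)
    amplitude = amplitude_from_minimum(f_g, kappa, h_min, env)
    return PotentialFit(
        gravitational_force=f_g,
        h_min=h_min,
        kappa=kappa,
        amplitude=amplitude,
        offset=offset,
        residual_norm=float(np.sqrt(np.mean(resid**2))),
        covariance=pcov,
        n_points=len(h),
    )
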