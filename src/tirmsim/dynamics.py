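"""Distance-resolved drift and diffusion from a trajectory or intensity trace.

The local drift velocity v(h) and normal diffusion coefficient D_n(h) are
estimated from conditional displacement moments: for each separation bin,
the mean and mean-squared displacement over lag times t = k*Delta_t are
collected from every window whose *starting* position falls in the bin
(overlapping windows, maximal statistics).  To first order in t,

    m(t, z)  = v(z) t + O(t^2)
    W(t, z)  = 2 D_n(z) t + O(t^2)

so straight-line fits of m and W against the first few lag times give v and
2 D_n as initial slopes.  (The second-order coefficients involve spatial
derivatives of v and D_n; the analysis here uses initial slopes only.)
Replicate simulation runs provide the error bars: per-bin means and standard
deviations across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .detect import IntensityTrace, OpticalModel
from .physics import MobilityModel, PotentialModel, drift_velocity_theory
from .simulate import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "DisplacementMoments",
    "DynamicsProfile",
    "trace_to_trajectory",
    "conditional_moments",
    "initial_slopes",
    "combine_replicates",
    "theory_overlay",
]

DEFAULT_BIN_WIDTH = 15.0  # nm
DEFAULT_MIN_OCCUPANCY = 1000  # samples per bin
DEFAULT_N_LAGS = 4
CLAMP_FLAG_FRACTION = 1e-3


@dataclass(frozen=True)
class DisplacementMoments:
    """Conditional displacement moments per separation bin and lag time."""

    bin_centers: np.ndarray  # nm
    lag_times: np.ndarray  # s, k*Delta_t for k = 1..max_lag
    mean: np.ndarray  # (n_lags, n_bins), nm
    mean_square: np.ndarray  # (n_lags, n_bins), nm^2
    occupancy: np.ndarray  # (n_bins,), windows at the longest lag


@dataclass(frozen=True)
class DynamicsProfile:
    """Distance-resolved drift velocity and normalized diffusion coefficient."""

    heights: np.ndarray  # nm
    velocity: np.ndarray  # um/s
    diffusion_ratio: np.ndarray  # D_n/D0
    velocity_sd: np.ndarray | None = None
    diffusion_sd: np.ndarray | None = None
    occupancy: np.ndarray | None = None


def trace_to_trajectory(
    trace: IntensityTrace,
    optics: OpticalModel | None = None,
    background_level: float = 0.0,
) -> Trajectory:
    """Invert an intensity trace sample-by-sample into separations (nm).

    ``background_level`` (kHz) is a constant count-rate offset subtracted
    before inversion — the standard calibration step when the background
    scattering level has been measured (e.g. with the probe particle moved
    away).  An *unsubtracted* background mean systematically compresses the
    recovered trajectory at large separations, where the signal no longer
    dominates the offset; the background's Poisson *fluctuations*, by
    contrast, are zero-mean and nearly harmless.

    Noise can push individual samples above the contact intensity I0 (which
    would map to negative separations); such samples are clamped to h = 0
    and counted.  If more than 0.1% of the samples clamp, a warning is
    logged — the trace is then too noisy, or I0 is miscalibrated.
    """
    optics = optics or trace.optics
    i0 = optics.intensity_at_contact
    v = trace.values - background_level
    n_over = int(np.count_nonzero(v > i0))
    n_zero = int(np.count_nonzero(v <= 0))
    if n_zero:
        # a zero photon count carries no distance information; map it to the
        # smallest representable signal (one count per interval)
        floor = 1.0 / (1e3 * trace.sampling_time * 1e-3)
        logger.warning("%d zero-count sample(s) mapped to 1 count", n_zero)
        v = np.maximum(v, floor)
    h = np.where(v >= i0, 0.0, optics.penetration_depth * np.log(i0 / np.maximum(v, 1e-300)))
    if n_over > CLAMP_FLAG_FRACTION * len(v):
        logger.warning(
            "%d/%d samples exceeded I0 and were clamped to h=0", n_over, len(v)
        )
    elif n_over:
        logger.info("%d sample(s) clamped to h=0", n_over)
    return Trajectory(trace.sampling_time, h)


def conditional_moments(
    traj: Trajectory,
    bin_width: float = DEFAULT_BIN_WIDTH,
    max_lag: int = DEFAULT_N_LAGS,
    min_occupancy: int = DEFAULT_MIN_OCCUPANCY,
) -> DisplacementMoments:
    """Mean and mean-squared displacement versus lag, conditioned on the
    starting separation.

    The bin is assigned from the position at the start of each lag window;
    windows overlap (every sample starts one).  Bins occupied by fewer than
    ``min_occupancy`` windows at the longest lag are dropped with a log
    message.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    h = traj.heights
    if len(h) <= max_lag:
        raise ValueError("trajectory shorter than max_lag")
    lo = np.floor(h.min() / bin_width) * bin_width
    idx = ((h - lo) / bin_width).astype(np.int64)
    n_bins = int(idx.max()) + 1
    centers = lo + bin_width * (np.arange(n_bins) + 0.5)

    mean = np.full((max_lag, n_bins), np.nan)
    mean_sq = np.full((max_lag, n_bins), np.nan)
    counts = np.zeros((max_lag, n_bins), dtype=np.int64)
    for k in range(1, max_lag + 1):
        start = idx[:-k]
        d = h[k:] - h[:-k]
        c = np.bincount(start, minlength=n_bins)
        s1 = np.bincount(start, weights=d, minlength=n_bins)
        s2 = np.bincount(start, weights=d * d, minlength=n_bins)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean[k - 1] = np.where(c > 0, s1 / np.maximum(c, 1), np.nan)
            mean_sq[k - 1] = np.where(c > 0, s2 / np.maximum(c, 1), np.nan)
        counts[k - 1] = c

    occ = counts.min(axis=0)
    keep = occ >= min_occupancy
    n_dropped = int(np.count_nonzero(~keep & (occ > 0)))
    if n_dropped:
        logger.info("dropped %d under-occupied separation bins", n_dropped)
    if not np.any(keep):
        raise ValueError("no separation bin reaches the occupancy threshold")
    dt_s = traj.sampling_time * 1e-3
    return DisplacementMoments(
        bin_centers=centers[keep],
        lag_times=dt_s * np.arange(1, max_lag + 1),
        mean=mean[:, keep],
        mean_square=mean_sq[:, keep],
        occupancy=occ[keep],
    )


def initial_slopes(
    moments: DisplacementMoments,
    n_lags: int = DEFAULT_N_LAGS,
    bulk_diffusion: float | None = None,
) -> DynamicsProfile:
    """Straight-line fits of m and W versus lag time; slopes are v and 2 D_n.

    Fits use the first ``n_lags`` lags with a free intercept (an intercept
    absorbs any residual localization-noise offset in W).  ``bulk_diffusion``
    (m^2/s) normalizes D_n to D_n/D0; if omitted, the raw D_n in m^2/s is
    reported in ``diffusion_ratio``.
    """
    if n_lags < 2:
        raise ValueError("need at least 2 lags for a slope")
    if n_lags > len(moments.lag_times):
        raise ValueError("fewer lags available than requested")
    t = moments.lag_times[:n_lags]
    design = np.vstack([t, np.ones_like(t)]).T
    coef_m, _, _, _ = np.linalg.lstsq(design, moments.mean[:n_lags], rcond=None)
    coef_w, _, _, _ = np.linalg.lstsq(design, moments.mean_square[:n_lags], rcond=None)
    v_um_s = coef_m[0] * 1e-3  # nm/s -> um/s
    dn_m2_s = 0.5 * coef_w[0] * 1e-18  # nm^2/s -> m^2/s
    ratio = dn_m2_s / bulk_diffusion if bulk_diffusion else dn_m2_s
    return DynamicsProfile(
        heights=moments.bin_centers,
        velocity=v_um_s,
        diffusion_ratio=ratio,
        occupancy=moments.occupancy,
    )


def combine_replicates(profiles: list[DynamicsProfile]) -> DynamicsProfile:
    """Average replicate dynamics profiles on their common separation bins.

    Returns per-bin means with standard deviations across replicates (the
    error-bar convention for repeated simulation runs).
    """
    if not profiles:
        raise ValueError("no profiles to combine")
    common = profiles[0].heights
    for p in profiles[1:]:
        common = np.intersect1d(common, p.heights)
    if common.size == 0:
        raise ValueError("replicates share no separation bins")
    v = np.stack([p.velocity[np.isin(p.heights, common)] for p in profiles])
    d = np.stack([p.diffusion_ratio[np.isin(p.heights, common)] for p in profiles])
    occ = np.stack(
        [
            p.occupancy[np.isin(p.heights, common)]
            if p.occupancy is not None
            else np.zeros_like(common)
            for p in profiles
        ]
    )
    ddof = 1 if len(profiles) > 1 else 0
    return DynamicsProfile(
        heights=common,
        velocity=v.mean(axis=0),
        diffusion_ratio=d.mean(axis=0),
        velocity_sd=v.std(axis=0, ddof=ddof),
        diffusion_sd=d.std(axis=0, ddof=ddof),
        occupancy=occ.sum(axis=0),
    )


def theory_overlay(
    h_grid,
    potential: PotentialModel,
    mobility: MobilityModel,
) -> DynamicsProfile:
    """Analytic v(h) (um/s) and D_n(h)/D0 on a separation grid (nm)."""
    h_grid = np.asarray(h_grid, dtype=float)
    v = np.asarray(drift_velocity_theory(h_grid, potential, mobility)) * 1e6
    ratio = np.asarray(mobility.mobility_ratio(h_grid))
    return DynamicsProfile(heights=h_grid, velocity=v, diffusion_ratio=ratio)
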