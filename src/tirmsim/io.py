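"""Plain-text readers and writers for traces, trajectories and profiles.

File conventions follow instrument practice: intensity traces are one
count-rate value (kHz) per line at a fixed sampling interval, with optional
``#``-prefixed ``key = value`` header lines carrying the metadata needed for
analysis (sampling time, contact intensity, penetration depth, seed, noise
flags).  The reader also accepts bare single-column deposits with the
metadata supplied by the caller.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .detect import IntensityTrace, OpticalModel
from .dynamics import DynamicsProfile
from .simulate import Trajectory
from .staticpot import PotentialFit, PotentialProfile

__all__ = [
    "write_trace",
    "read_trace",
    "write_trajectory",
    "read_trajectory",
    "write_profile",
    "read_profile",
    "write_fit",
    "write_dynamics",
]


def write_trace(path, trace: IntensityTrace, seed: int | None = None) -> None:
    """Write a trace as one kHz value per line with metadata headers."""
    path = Path(path)
    lines = [
        "# tirmsim intensity trace (kHz per line)",
        f"# sampling_time_ms = {trace.sampling_time!r}",
        f"# intensity_at_contact_kHz = {trace.optics.intensity_at_contact!r}",
        f"# penetration_depth_nm = {trace.optics.penetration_depth!r}",
        f"# noise_flags = {','.join(trace.noise_flags) or 'none'}",
    ]
    if seed is not None:
        lines.append(f"# seed = {seed}")
    body = "\n".join(f"{v:.6f}" for v in trace.values)
    path.write_text("\n".join(lines) + "\n" + body + "\n")


def read_trace(
    path,
    sampling_time: float | None = None,
    optics: OpticalModel | None = None,
) -> IntensityTrace:
    """Read a single-column intensity trace (kHz per line).

    Header metadata, when present, populates the sampling time and optics;
    explicit arguments override it.  A file with no metadata requires both
    ``sampling_time`` and ``optics`` (the conversion to separations is
    undefined without I0 and the penetration depth).
    """
    path = Path(path)
    meta: dict[str, str] = {}
    values: list[float] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" in line:
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
            continue
        try:
            values.append(float(line.split()[0]))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: cannot parse {line!r}") from exc
    if not values:
        raise ValueError(f"{path}: no samples found")
    if sampling_time is None:
        if "sampling_time_ms" not in meta:
            raise ValueError(f"{path}: sampling time neither in header nor supplied")
        sampling_time = float(meta["sampling_time_ms"])
    if optics is None:
        if "intensity_at_contact_kHz" not in meta or "penetration_depth_nm" not in meta:
            raise ValueError(
                f"{path}: optics (I0, penetration depth) neither in header nor "
                "supplied; separations cannot be computed without them"
            )
        optics = OpticalModel(
            float(meta["intensity_at_contact_kHz"]),
            float(meta["penetration_depth_nm"]),
        )
    flags = tuple(
        f for f in meta.get("noise_flags", "").split(",") if f and f != "none"
    )
    return IntensityTrace(sampling_time, np.array(values), optics, flags)


def write_trajectory(path, traj: Trajectory, compact: bool = True) -> None:
    """Write a trajectory; compact = one h (nm) per line with the sampling
    time in a header, otherwise two columns (time s, h nm)."""
    path = Path(path)
    header = [
        "# tirmsim trajectory",
        f"# sampling_time_ms = {traj.sampling_time!r}",
    ]
    if compact:
        body = "\n".join(f"{h:.6f}" for h in traj.heights)
    else:
        header.append("# columns = time_s h_nm")
        body = "\n".join(
            f"{t:.6f}\t{h:.6f}" for t, h in zip(traj.times, traj.heights)
        )
    path.write_text("\n".join(header) + "\n" + body + "\n")


def read_trajectory(path, sampling_time: float | None = None) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory` (either layout)."""
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" in line:
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
            continue
        try:
            rows.append([float(x) for x in line.split()])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: cannot parse {line!r}") from exc
    if not rows:
        raise ValueError(f"{path}: no samples found")
    if sampling_time is None:
        if "sampling_time_ms" in meta:
            sampling_time = float(meta["sampling_time_ms"])
        elif len(rows[0]) == 2 and len(rows) > 1:
            sampling_time = (rows[1][0] - rows[0][0]) * 1e3
        else:
            raise ValueError(f"{path}: sampling time neither in header nor supplied")
    heights = np.array([r[-1] for r in rows])
    return Trajectory(sampling_time, heights)


def write_profile(path, profile: PotentialProfile) -> None:
    """Potential profile as CSV: h_nm, dphi_kT, sigma_kT, counts."""
    path = Path(path)
    lines = [
        f"# h_ref_nm = {profile.h_ref!r}",
        f"# bin_width_kHz = {profile.bin_width!r}",
        f"# min_count = {profile.min_count}",
        "h_nm,dphi_kT,sigma_kT,counts",
    ]
    for h, p, s, c in zip(profile.heights, profile.dphi, profile.sigma, profile.counts):
        lines.append(f"{h:.4f},{p:.6f},{s:.6f},{int(c)}")
    path.write_text("\n".join(lines) + "\n")


def read_profile(path) -> PotentialProfile:
    path = Path(path)
    meta: dict[str, str] = {}
    data: list[list[float]] = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("h_nm"):
            continue
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition("=")
            meta[key.strip()] = val.strip()
            continue
        data.append([float(x) for x in line.split(",")])
    arr = np.array(data)
    return PotentialProfile(
        heights=arr[:, 0],
        dphi=arr[:, 1],
        sigma=arr[:, 2],
        h_ref=float(meta.get("h_ref_nm", "nan")),
        counts=arr[:, 3].astype(int),
        bin_width=float(meta.get("bin_width_kHz", "1.0")),
        min_count=int(meta.get("min_count", "20")),
    )


def write_fit(path, fit: PotentialFit, extra: dict | None = None) -> None:
    """Fit parameters and diagnostics as JSON."""
    payload = {
        "gravitational_force_fN": fit.gravitational_force,
        "h_min_nm": fit.h_min,
        "debye_length_nm": fit.debye_length,
        "amplitude_kT": fit.amplitude,
        "offset_kT": fit.offset,
        "residual_norm_kT": fit.residual_norm,
        "n_points": fit.n_points,
        "covariance": np.asarray(fit.covariance).tolist(),
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_dynamics(path, profile: DynamicsProfile) -> None:
    """Dynamics profile as CSV: h_nm, v_um_s, v_sd, Dn_over_D0, Dn_sd, occupancy."""
    path = Path(path)
    n = len(profile.heights)
    v_sd = profile.velocity_sd if profile.velocity_sd is not None else np.full(n, np.nan)
    d_sd = profile.diffusion_sd if profile.diffusion_sd is not None else np.full(n, np.nan)
    occ = profile.occupancy if profile.occupancy is not None else np.zeros(n)
    lines = ["h_nm,v_um_s,v_sd,Dn_over_D0,Dn_sd,occupancy"]
    for i in range(n):
        lines.append(
            f"{profile.heights[i]:.4f},{profile.velocity[i]:.6g},{v_sd[i]:.6g},"
            f"{profile.diffusion_ratio[i]:.6g},{d_sd[i]:.6g},{int(occ[i])}"
        )
    path.write_text("\n".join(lines) + "\n")
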