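"""Numba-compiled Brownian-dynamics inner loops.

The trajectory update is inherently sequential (each displacement depends on
the position-dependent mobility at the current position), so the hot loop is
JIT-compiled.  All quantities inside the kernels are SI; the Gaussian draws
are generated outside with a seeded numpy Generator so that trajectories are
reproducible bit-for-bit regardless of compilation details.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STICK = 0
PARTIAL_SLIP = 1


@njit(cache=False)
def bd_trajectory(
    h0: float,
    n: int,
    dt: float,
    b_joule: float,
    kappa: float,
    f_g: float,
    radius: float,
    d0: float,
    beta: float,
    mobility_kind: int,
    ca: float,
    cb: float,
    cc: float,
    cd: float,
    drift_scale: float,
    theta: np.ndarray,
):
    """Iterate the overdamped displacement update with spurious-drift term.

    Delta_z = beta*D_n*(-dphi/dh)*dt + (dD_n/dz)*dt*drift_scale
              + theta*sqrt(2*D_n*dt)

    h0 in m; returns n positions in m, the first being h0.  drift_scale is
    1.0 for physical dynamics; 0.0 switches the dD/dz correction off (used
    only to demonstrate that the term is required for Boltzmann sampling).
    Positions reflecting below the wall are folded back (h <- -h).
    """
    out = np.empty(n)
    out[0] = h0
    h = h0
    n_reflect = 0
    for i in range(1, n):
        # dphi/dh = F_g - B*kappa*exp(-kappa*h)
        dphi = f_g - b_joule * kappa * np.exp(-kappa * h)
        if mobility_kind == STICK:
            num = 6.0 * h * h + 2.0 * h * radius
            den = 6.0 * h * h + 9.0 * h * radius + 2.0 * radius * radius
            d = d0 * num / den
            dd = (
                d0
                * ((12.0 * h + 2.0 * radius) * den - num * (12.0 * h + 9.0 * radius))
                / (den * den)
            )
        else:
            eps = h / radius
            leps = np.log(eps)
            bracket = ca / eps - cb * leps + cc - cd * eps * leps
            d = d0 / bracket
            dbracket = -ca / (eps * eps) - cb / eps - cd * (leps + 1.0)
            dd = -d0 * dbracket / (bracket * bracket) / radius
        h += (
            -beta * d * dphi * dt
            + drift_scale * dd * dt
            + theta[i - 1] * np.sqrt(2.0 * d * dt)
        )
        if h <= 0.0:
            h = -h
            n_reflect += 1
        out[i] = h
    return out, n_reflect
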