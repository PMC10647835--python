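# tirmsim

Simulation and analysis of **total internal reflection microscopy (TIRM)**
experiments on a single colloidal sphere near a flat wall.

TIRM infers the instantaneous wall separation `h` of a micron-sized probe
sphere from the light it scatters out of an evanescent field,
`I(h) = I0 exp(-Λh)`, and turns a long intensity time trace into two kinds
of results:

* the **static interaction potential** `φ(h) = B e^{-κh} + F_g h`
  (screened double-layer repulsion plus buoyant weight), via Boltzmann
  inversion of the intensity histogram and a nonlinear fit of
  `Δφ(h) = (F_g/κ)[e^{-κ(h-h_min)} - 1] + F_g (h - h_min)`,
  resolving femtonewton forces;
* **distance-resolved dynamics** — drift velocity `v(h)` and normal
  diffusion coefficient `D_n(h)` — from the initial slopes of conditional
  mean and mean-squared displacements, compared against hindered-diffusion
  theory for stick (`D_n/D_0 = (6h²+2hR)/(6h²+9hR+2R²)`) or partial-slip
  boundary conditions.

The package is aimed at experimenters who want to know *when to trust such
measurements*: it generates fully synthetic photon-count traces (overdamped
Brownian dynamics with position-dependent mobility via the Ermak–Buckholz
scheme, Poisson shot noise, additive Poisson background) and quantifies how
detector noise and the choice of sampling time bias the recovered potentials
and mobilities — including the rule of thumb
`Δt_max = Δh·6πηR/(|∂φ/∂h|·λ⁻¹)` for picking particle size and sampling
time. See `docs/methods.md` for the full model description.

## Worked example

Simulate the benchmark bead (3 µm polystyrene sphere in 1 mM NaCl,
`B = 1167 k_BT`, `κ⁻¹ = 10.2 nm`, `F_g = 64 fN`), corrupt the trace with
shot noise plus 5% background, and fit the reconstructed potential:

```python
import numpy as np
from tirmsim import *

env = Environment()                      # water at 293 K, 3 um bead
bead = PotentialModel.from_debye_length( # B (kT), kappa^-1 (nm), F_g (fN)
    1167.0, 10.2, 64.0)
optics = OpticalModel()                  # I0 = 1595 kHz, depth 200.4 nm

cfg = SimulationConfig(n_points=1_000_000, sampling_time=2.0,
                       potential=bead, seed=1)
traj = simulate_trajectory(cfg)
trace = IntensityTrace(2.0, intensity_from_height(traj.heights, optics), optics)
rng = np.random.default_rng(10001)
trace = apply_background_noise(apply_shot_noise(trace, rng), 0.05, rng)

profile = profile_from_histogram(build_histogram(trace, 1.0), optics)
fit = fit_profile(profile, env)
print(f"F_g      = {fit.gravitational_force:5.1f} fN   (input 64)")
print(f"h_min    = {fit.h_min:5.1f} nm   (input 90.6)")
print(f"kappa^-1 = {fit.debye_length:5.2f} nm  (input 10.2)")
print(f"B        = {fit.amplitude:5.0f} kT   (input 1167)")
```

Output:

```
F_g      =  69.1 fN   (input 64)
h_min    =  85.2 nm   (input 90.6)
kappa^-1 = 12.59 nm  (input 10.2)
B        =   187 kT   (input 1167)
```

This single run already shows the systematic fingerprints of detector
noise: the gravitational force comes out a few fN high (the unsubtracted
background mean compresses the distance axis), the apparent screening
length is inflated (shot noise smears the steep repulsive rise), and the
electrostatic amplitude — exponentially sensitive to `h_min` — is strongly
underestimated. A noise-free trace at ten-fold shorter sampling time
recovers all inputs within a few percent. The same analyses run from the
shell:

```bash
tirmsim simulate --n-points 1000000 --seed 1 --out trace.txt
tirmsim corrupt trace.txt --background 0.05 --out noisy.txt
tirmsim potential noisy.txt --profile-out profile.csv --fit-out fit.json
tirmsim dynamics noisy.txt --out dynamics.csv
tirmsim design-check --sampling-time 2.0
tirmsim experiment --outdir run/ --replicates 5
```

Stored experimental traces (plain text, one count rate in kHz per line) are
analysed with the identical code path via `tirmsim analyze`, given the
sampling time, contact intensity `I0` and penetration depth.

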