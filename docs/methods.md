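# Methods

`tirmsim` models a total internal reflection microscopy (TIRM) experiment on
a single colloidal sphere near a flat wall, end to end: the physics of the
particle, the optics of the detection, the statistics of photon counting,
and the two inverse problems (static potential, local dynamics) that the
technique solves. This note records the model, the numerical choices, and
the limits of what the synthetic data can show.

## Physical model

**Wall potential.** The sphere interacts with the wall through a DLVO-type
potential

    phi(h) = B exp(-kappa h) + F_g h

with surface separation `h`, electrostatic amplitude `B` (k_BT), inverse
Debye screening length `kappa` (1/nm) and buoyancy-corrected weight `F_g`
(fN). The minimum sits at `h_min = ln(kappa B / F_g) / kappa`; the same
relation is used in reverse to recover `B` from a fitted `(F_g, kappa,
h_min)` triple, because the steep repulsive branch is never sampled well
enough to fit `B` directly. Van der Waals and depletion terms are not
implemented; the potential interface accepts `B = 0` (pure gravity) but no
other functional forms.

**Hydrodynamics.** Normal-to-wall diffusion is hindered by the wall. Two
mobility laws are available:

* *stick*: the Pade-type approximation to the exact series solution,
  `D_n/D_0 = (6h^2 + 2hR) / (6h^2 + 9hR + 2R^2)`, valid at all separations,
  with `D_0 = k_BT / 6 pi eta R`;
* *partial slip*: the lubrication expansion
  `D_n = D_0 / (A/eps - B ln eps + C - D eps ln eps)`, `eps = h/R`, with
  coefficient rows shipped for slip parameters `zeta = 1/12, 0.12, 1/3`
  (`A = 1/4` in all rows; slip length `l_s = zeta R / (1 - 3 zeta)`).

The partial-slip friction bracket is dimensionless; this package normalizes
it by the Stokes coefficient `6 pi eta R`, which makes the expression
dimensionally consistent and of the same order as the stick lubrication
limit. The expansion is only meaningful for small gaps; calls above
`eps = 0.3` warn. Both mobilities expose analytic derivatives `dD_n/dz`
(closed-form differentiation, verified against central differences at
1e-6 relative tolerance): the derivative enters the simulation drift term,
and numerical differentiation noise there would bias equilibrium sampling.

**Drift velocity.** `v(z) = dD_n/dz - beta D_n dphi/dh`: a force-driven term
plus the spurious drift required by the position dependence of the mobility.
Far from the wall with gravity only it reduces to the Stokes settling
velocity `-F_g / 6 pi eta R` (~1.1 um/s for the benchmark bead).

## Simulator

Overdamped one-dimensional Brownian dynamics with the Ermak–Buckholz
discretization:

    Delta z = beta D_n (-dphi/dh) dt + (dD_n/dz) dt + Theta sqrt(2 D_n dt)

`Theta` is standard Gaussian (unit variance is forced by the explicit
`sqrt(2 D dt)` factor). Forces and mobility are held constant within a
step, exactly as the instrument's sampling assumes. Dropping the `dD_n/dz`
term demonstrably breaks Boltzmann sampling (a regression test switches it
off and asserts the Kolmogorov–Smirnov test then fails).

The start position is the Boltzmann-weighted mean of a configurable grid
(default 1–800 nm, 0.5 nm steps). Note the field often calls this "the most
probable position"; the defining formula is the weighted mean, which for the
benchmark parameters lies ~48 nm above `h_min` because of the exponential
gravity tail (decay length `k_BT/F_g` ≈ 63 nm). Trajectories are reflected
at `h = 0` as a numerical safeguard; with repulsive parameter sets the event
essentially never occurs, and occurrences are logged.

The sequential hot loop is JIT-compiled (numba); the Gaussian stream is
drawn beforehand from `numpy.random.default_rng(seed)`, so a configuration
plus seed reproduces every sample bit-for-bit. Replicate campaigns use
consecutive seeds `master+0 … master+r-1`. A 10^6-step trajectory takes a
fraction of a second.

## Detection and noise

Scattered intensity couples to separation as `I(h) = I0 exp(-Lambda h)`;
defaults are the calibrated values `I0 = 1595 kHz`, penetration depth
`Lambda^-1 = 200.4 nm` (alternatively derived from indices, incidence angle
and wavelength). Two noise sources:

* *Shot noise*: each sample's expected photon count `n = I dt` is replaced
  by a Poisson draw. Statistics act on integer counts per sampling interval,
  not on kHz values — the photomultiplier counts photons, and this
  reproduces the 1-count granularity (0.5 kHz at 2 ms) of real traces. At
  the operating range (≥500 kHz, 2 ms) the induced per-sample height error
  `Lambda^-1/sqrt(n)` is 4–9 nm.
* *Background*: scattering from everything that is not the probe, modeled
  as an added independent Poisson count with mean `f_bg * <I_test> * dt`,
  where `<I_test>` is the mean of the first 10^4 samples and `f_bg` (default
  0.05) is the background-to-signal ratio. A well-aligned instrument keeps
  `f_bg` below 0.05.

An important and easily overlooked consequence, quantified by this package:
the background's *mean* is a deterministic offset, not noise. Inverting a
trace through `h = ln(I0/I)/Lambda` without subtracting it compresses the
distance axis where the signal is weak (at 400 nm separation a 5% background
shrinks apparent displacements by ~16%, hence apparent `D_n` by ~30%) and
rigidly shifts the reconstructed potential by several nm. The background
*fluctuations* are zero-mean and nearly harmless. `trace_to_trajectory`
therefore accepts a `background_level` to subtract — the standard
calibration step when the background has been measured — and the experiment
pipeline uses the known simulated level by default
(`subtract_background: true`). The static-potential pipeline deliberately
does *not* subtract, matching common practice; the resulting few-fN upward
bias of the fitted `F_g` is part of what the noise study quantifies.

## Static potential reconstruction

1. Histogram the count rates with 1 kHz bins (the count-rate resolution at
   2 ms); bin edges are aligned to multiples of the width.
2. The most frequent intensity defines the reference `I_ref` (ties resolve
   toward lower intensity, i.e. larger separation; logged). Its separation
   `h_ref = ln(I0/I_ref)/Lambda` exceeds `h_min` because the histogram
   maximum is displaced by the photon-side Jacobian weighting `Lambda k_BT`;
   the closed-form ratio `h_min/h_ref = ln(kappa B/F_g) / ln(kappa B/(F_g -
   Lambda k_BT))` is ≈0.95 for typical parameters.
3. Boltzmann inversion per bin with the Jacobian applied through the
   product `I N(I)`: `Delta phi/k_BT = -ln[(I N(I)) / (I_ref N(I_ref))]`.
   Bins rarer than 20 counts per 10^6 samples are dropped (the threshold
   scales with trace length so that the working range stays ~10 k_BT above
   the minimum); counting uncertainties `sqrt(1/N + 1/N_ref)` are attached
   to every point. Temporal correlation of the trajectory (position
   relaxation ~0.1–0.4 s vs 2 ms sampling) inflates the realized scatter
   above this independent-sample estimate, which matters for goodness-of-fit
   judgements.
4. Nonlinear least squares of
   `Delta phi = (F_g/kappa)[exp(-kappa(h-h_min)) - 1] + F_g (h-h_min) + c`
   with `(F_g, h_min, kappa, c)` floating, bounds keeping the physical
   parameters positive. The free offset `c` is not part of the physical
   model — the profile is pinned to zero at `h_ref` by construction — but
   bin discretization makes it numerically safer. Initialization: `F_g` from
   the slope of the outer 30% of points, `h_min` from the argmin, `kappa`
   from the nominal salt concentration (`kappa^-1 = 0.304/sqrt(c_s)` nm).
   The fit is unweighted by default; `weighted=True` uses the counting
   uncertainties. Non-convergence surfaces as an exception from the
   optimizer, never silently.

Profile *shapes* are compared with `compare_profiles`, which registers out a
rigid distance-axis shift (≤20 nm) before computing residuals, because
background offsets and the bin-discrete reference choice move the absolute
axis without altering the shape.

## Dynamics extraction

Conditional displacement moments: for each 15 nm separation bin, the mean
`m` and mean-square `W` of displacements over lags `k dt`, `k = 1…4`,
conditioned on the *measured start position* of each (overlapping) window.
Straight-line fits of `m` and `W` versus lag time with a free intercept give
`v` and `2 D_n` as initial slopes; the intercept absorbs the constant
localization-noise offset `2 sigma_h^2` in `W`. Second-order terms in the
short-time expansions (they involve spatial derivatives of `v` and `D_n`)
are not estimated. Bins with fewer than 10^3 windows are dropped. Error
bars come from replicate runs (mean ± sd across seeds), not from per-bin
analytic formulas.

Known estimator limitations, measured with this package:

* In the steep-force region (wall force ≳ 0.5–1 pN, `h` ≲ 70 nm for the
  benchmark bead) shot noise mixes positions across bins of a steeply
  varying density, inflating apparent `D_n` by up to ~50% in the lowest bin.
  Outside that region, full noise and no noise agree within replicate
  scatter — the symmetric-Poisson argument for noise insensitivity holds.
* At 2 ms sampling, the constant-force assumption fails where the drift
  moves the particle further than the local height resolution within one
  interval; apparent `D_n` then deviates from theory at the smallest
  separations (upward for stick under strong confinement-free drift). A
  ten-fold shorter sampling time removes the deviation.
* With partial-slip mobility at 2 ms, mid-small separations (~80–110 nm)
  fall below the slip prediction toward the stick curve; 0.1 ms restores
  the slip theory. In the very lowest bin the competing drift-squared
  contamination of `W` can instead push the estimate above theory; both
  artifacts share the same cause (too much motion per sampling interval).

## Experiment design rule

`max_sampling_time` evaluates `Delta t_max = Delta h 6 pi eta R /
(|dphi/dh| lambda^-1(h))` — the time in which the force-driven drift covers
the height resolution `Delta h`. The `design_check` scan uses the
position-dependent resolution `Delta h(h) = Lambda^-1 ΔI / I(h)` implied by
the 1 kHz count-rate resolution (~0.2 nm where the signal is strong,
coarser in the tail); for the benchmark bead at 2 ms it flags the steep
region below ~70 nm, and at 0.2 ms nothing above 50 nm.

## What the synthetic data do and do not show

The generator reproduces the statistical structure of real traces —
Boltzmann statistics with hindered diffusion, exponential optics, Poisson
counting, configurable background — under the reference conditions (10^6
samples at 2 ms, count rates 0.5–1.6 MHz, 3 um bead in water at 293 K,
1 mM 1:1 electrolyte). It does not model: lateral motion or tweezer forces,
detector dead time, penetration-depth miscalibration, non-exponential
scattering of rough or non-spherical particles, or bead-to-bead variation
within one trace. Passing tests therefore validate the estimators under the
stated model, not the optical calibration of a particular instrument.

Problem sizes in the test suite follow the reference protocol: 10^6-sample
traces, five replicate seeds; the short-sampling-time recovery check keeps
the physical duration (2000 s) rather than the sample count, i.e. 10^7
samples at 0.2 ms, because the gravitational tail statistics — and hence the
fitted `F_g` — are controlled by the number of independent barrier
excursions, not by the number of correlated samples.

## Open choices made here

* The partial-slip normalization (`6 pi eta R`), as discussed above.
* The background model is parameterized by the background-to-signal ratio
  `f_bg` rather than a signal-to-noise ratio, whose printed form is
  ambiguous for strong signals; `f_bg` is fully configurable and 0.05 is
  the default working point.
* The `zeta = 1/3` slip row is shipped as tabulated; no independent check
  of those three coefficients exists here.
* Fit weighting defaults to unweighted; the counting uncertainties are
  reported so the weighted variant is one flag away.
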