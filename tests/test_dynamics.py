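"""Conditional displacement moments and initial-slope estimators."""

from __future__ import annotations

import numpy as np
import pytest

from tirmsim import (
    IntensityTrace,
    MobilityModel,
    SlipCoefficients,
    Trajectory,
    apply_shot_noise,
    combine_replicates,
    conditional_moments,
    diffusion_stick,
    initial_slopes,
    intensity_from_height,
    minimum_position,
    theory_overlay,
    trace_to_trajectory,
)
from tirmsim.dynamics import DisplacementMoments


class TestTraceInversion:
    def test_noise_free_round_trip(self, traj_p3, optics):
        trace = IntensityTrace(2.0, intensity_from_height(traj_p3.heights, optics), optics)
        back = trace_to_trajectory(trace, optics)
        np.testing.assert_allclose(back.heights, traj_p3.heights, rtol=1e-12)

    def test_constant_intensity(self, optics):
        trace = IntensityTrace(
            2.0, np.full(10, optics.intensity_at_contact / np.e), optics
        )
        traj = trace_to_trajectory(trace, optics)
        np.testing.assert_allclose(traj.heights, optics.penetration_depth, rtol=1e-12)

    def test_noisy_scatter_matches_error_propagation(self, optics, rng):
        h0 = 150.0
        i0 = intensity_from_height(h0, optics)
        n = i0 * 1e3 * 2e-3
        trace = apply_shot_noise(
            IntensityTrace(2.0, np.full(30_000, i0), optics), rng
        )
        traj = trace_to_trajectory(trace, optics)
        assert traj.heights.std() == pytest.approx(
            optics.penetration_depth / np.sqrt(n), rel=0.05
        )

    def test_over_contact_samples_clamped(self, optics):
        vals = np.array([optics.intensity_at_contact * 1.2, 500.0, 500.0])
        traj = trace_to_trajectory(IntensityTrace(2.0, vals, optics), optics)
        assert traj.heights[0] == 0.0
        assert np.all(traj.heights[1:] > 0)

    def test_background_offset_compresses_large_separations(self, traj_p3, optics):
        # an unsubtracted constant background shrinks apparent separations
        # (and displacements) where the signal is weak; subtracting the known
        # level restores the trajectory
        bg = 45.0
        vals = intensity_from_height(traj_p3.heights, optics) + bg
        biased = trace_to_trajectory(IntensityTrace(2.0, vals, optics), optics)
        fixed = trace_to_trajectory(
            IntensityTrace(2.0, vals, optics), optics, background_level=bg
        )
        far = traj_p3.heights > 300
        assert np.all(biased.heights[far] < traj_p3.heights[far])
        np.testing.assert_allclose(fixed.heights, traj_p3.heights, rtol=1e-9)


class TestConditionalMoments:
    def test_free_diffusion_moments(self, rng):
        # iid Gaussian random walk: W(k dt) = 2 D k dt, m = 0
        d_nm2_s = 5e4  # nm^2/s
        dt = 2e-3
        steps = rng.normal(0.0, np.sqrt(2 * d_nm2_s * dt), 400_000)
        h = 5e4 + np.cumsum(steps)
        mom = conditional_moments(Trajectory(2.0, h), bin_width=1e6, max_lag=4,
                                  min_occupancy=10)
        prof = initial_slopes(mom, 4)
        assert prof.velocity[0] == pytest.approx(0.0, abs=0.5)
        assert prof.diffusion_ratio[0] == pytest.approx(d_nm2_s * 1e-18, rel=0.02)

    def test_deterministic_drift(self):
        c = 3.0  # nm per sample
        h = 1000.0 + c * np.arange(50_000)
        mom = conditional_moments(Trajectory(1.0, h), bin_width=1e9, max_lag=4,
                                  min_occupancy=10)
        for k in range(4):
            assert mom.mean[k, 0] == pytest.approx(c * (k + 1), rel=1e-9)
            assert mom.mean_square[k, 0] == pytest.approx((c * (k + 1)) ** 2, rel=1e-9)
        prof = initial_slopes(mom, 4)
        assert prof.velocity[0] == pytest.approx(3.0, rel=1e-9)  # um/s

    def test_msd_reproduces_stick_mobility(self, traj_p3, env):
        mom = conditional_moments(traj_p3, bin_width=15.0, max_lag=1,
                                  min_occupancy=3000)
        for i, h in enumerate(mom.bin_centers):
            if 90.0 < h < 200.0:
                d_est = mom.mean_square[0, i] / (2 * 2e-3) * 1e-18
                assert d_est == pytest.approx(diffusion_stick(h, env), rel=0.1)

    def test_too_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            conditional_moments(Trajectory(1.0, np.ones(3)), max_lag=5)


class TestInitialSlopes:
    def test_exact_linear_input(self):
        t = 1e-3 * np.arange(1, 5)
        mom = DisplacementMoments(
            bin_centers=np.array([100.0]),
            lag_times=t,
            mean=(2000.0 * t)[:, None],  # nm: v = 2 um/s
            mean_square=(2 * 7e4 * t + 5.0)[:, None],  # offset absorbed
            occupancy=np.array([10_000]),
        )
        prof = initial_slopes(mom, 4, bulk_diffusion=7e-14)
        assert prof.velocity[0] == pytest.approx(2.0, rel=1e-9)
        assert prof.diffusion_ratio[0] == pytest.approx(7e4 * 1e-18 / 7e-14, rel=1e-9)

    def test_requested_lags_validated(self):
        mom = DisplacementMoments(
            np.array([1.0]), 1e-3 * np.arange(1, 3),
            np.zeros((2, 1)), np.zeros((2, 1)), np.array([100]),
        )
        with pytest.raises(ValueError):
            initial_slopes(mom, 5)
        with pytest.raises(ValueError):
            initial_slopes(mom, 1)

    def test_replicate_combination(self):
        p1 = _profile([100.0, 115.0], [1.0, 2.0], [0.5, 0.6])
        p2 = _profile([100.0, 115.0, 130.0], [3.0, 4.0, 9.0], [0.7, 0.8, 0.9])
        combo = combine_replicates([p1, p2])
        np.testing.assert_allclose(combo.heights, [100.0, 115.0])
        np.testing.assert_allclose(combo.velocity, [2.0, 3.0])
        np.testing.assert_allclose(combo.diffusion_ratio, [0.6, 0.7])
        assert combo.velocity_sd is not None


def _profile(h, v, d):
    from tirmsim.dynamics import DynamicsProfile

    h = np.asarray(h, dtype=float)
    return DynamicsProfile(
        heights=h,
        velocity=np.asarray(v, dtype=float),
        diffusion_ratio=np.asarray(d, dtype=float),
        occupancy=np.full(h.size, 10),
    )


class TestTheoryOverlay:
    def test_far_field_limits(self, particle3, stick_mobility, env):
        prof = theory_overlay(np.array([2e6]), particle3, stick_mobility)
        assert prof.diffusion_ratio[0] == pytest.approx(1.0, rel=5e-3)
        assert prof.velocity[0] == pytest.approx(-64e-15 / env.stokes_drag * 1e6,
                                                 rel=5e-3)

    def test_slip_curve_above_stick(self, particle3, env, stick_mobility):
        slip = MobilityModel(
            "partial_slip", env, SlipCoefficients.from_slip_parameter(1 / 12)
        )
        h = np.linspace(10.0, 300.0, 100)
        d_slip = theory_overlay(h, particle3, slip).diffusion_ratio
        d_stick = theory_overlay(h, particle3, stick_mobility).diffusion_ratio
        assert np.all(d_slip > d_stick)

    def test_positive_spurious_drift_at_minimum(self, particle3, stick_mobility, env):
        h_min = minimum_position(particle3, env)
        prof = theory_overlay(np.array([h_min]), particle3, stick_mobility)
        assert 0 < prof.velocity[0] < 0.1  # um/s, small and positive
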