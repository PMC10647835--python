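"""Closed-form physics: potentials, forces, mobilities, design helpers."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tirmsim import (
    Environment,
    MobilityModel,
    PotentialModel,
    SlipCoefficients,
    amplitude_from_minimum,
    buoyant_weight,
    debye_length_from_salt,
    diffusion_slip,
    diffusion_stick,
    drift_velocity_theory,
    hmin_over_href,
    max_sampling_time,
    minimum_position,
    potential_energy,
    slip_length,
    wall_force,
)
from tirmsim.physics import (
    SLIP_TABLE,
    diffusion_slip_derivative,
    diffusion_stick_derivative,
    stick_mobility_ratio,
)

KT_293 = 1.380649e-23 * 293.0


class TestPotential:
    def test_pure_gravity_is_linear(self, env):
        model = PotentialModel(0.0, 0.1, 50.0)
        h = np.array([0.0, 100.0, 200.0])
        expected = 50.0e-15 * h * 1e-9 / env.kT
        np.testing.assert_allclose(potential_energy(h, model, env), expected)

    def test_gravity_dominates_far_from_wall(self, particle3, env):
        # at 200 nm the screened repulsion is < 1e-5 kT
        val = potential_energy(200.0, particle3, env)
        grav = 64.0e-15 * 200e-9 / env.kT
        assert abs(val - grav) < 1e-5
        assert val == pytest.approx(3.164, rel=1e-3)

    def test_force_vanishes_at_minimum(self, particle3, env):
        h_min = minimum_position(particle3, env)
        assert wall_force(h_min, particle3, env) == pytest.approx(0.0, abs=1e-20)

    def test_repulsion_about_a_piconewton_at_60nm(self, particle3, env):
        # the steep-region benchmark: ~1 pN at 60 nm, ~3.4 pN at 50 nm
        assert wall_force(60.0, particle3, env) == pytest.approx(1.23e-12, rel=0.01)
        assert wall_force(50.0, particle3, env) == pytest.approx(3.38e-12, rel=0.01)

    def test_negative_separation_rejected(self, particle3):
        with pytest.raises(ValueError):
            potential_energy(-1.0, particle3)
        with pytest.raises(ValueError):
            wall_force(-1.0, particle3)


class TestMinimum:
    def test_benchmark_minimum_near_91nm(self, env):
        model = PotentialModel.from_debye_length(1167.0, 10.24, 64.0)
        assert minimum_position(model, env) == pytest.approx(91.0, abs=0.5)

    def test_ln_e_identity(self, env):
        # kappa B = F_g * e with kappa = 1/nm puts the minimum at exactly 1 nm
        f_g = 50.0
        b_kt = np.e * f_g * 1e-15 * 1e-9 / env.kT
        model = PotentialModel(b_kt, 1.0, f_g)
        assert minimum_position(model, env) == pytest.approx(1.0, rel=1e-12)

    def test_doubling_amplitude_shifts_by_ln2_over_kappa(self, particle3, env):
        h1 = minimum_position(particle3, env)
        doubled = PotentialModel(2 * particle3.amplitude, particle3.kappa,
                                 particle3.gravitational_force)
        h2 = minimum_position(doubled, env)
        assert h2 - h1 == pytest.approx(np.log(2.0) / particle3.kappa, rel=1e-12)

    def test_no_minimum_raises(self, env):
        with pytest.raises(ValueError, match="no minimum"):
            minimum_position(PotentialModel(1e-6, 0.1, 50.0), env)

    @given(
        b=st.floats(200.0, 5000.0),
        kappa_inv=st.floats(5.0, 20.0),
        f_g=st.floats(30.0, 90.0),
    )
    def test_amplitude_minimum_round_trip(self, b, kappa_inv, f_g):
        env = Environment()
        model = PotentialModel.from_debye_length(b, kappa_inv, f_g)
        h_min = minimum_position(model, env)
        assert amplitude_from_minimum(f_g, model.kappa, h_min, env) == pytest.approx(
            b, rel=1e-10
        )

    def test_amplitude_at_zero_minimum(self, env):
        # h_min = 0 collapses the relation to F_g/kappa
        expected = 64e-15 * 10.2e-9 / env.kT
        assert amplitude_from_minimum(64.0, 1 / 10.2, 0.0, env) == pytest.approx(
            expected, rel=1e-12
        )


class TestHistogramShift:
    """Ratio h_min/h_ref between potential minimum and histogram reference."""

    def test_typical_parameters_give_095(self, env):
        model = PotentialModel.from_debye_length(1000.0, 10.0, 50.0)
        assert hmin_over_href(model, 1 / 200.0, env) == pytest.approx(0.95, abs=0.005)

    def test_limit_of_deep_penetration(self, env):
        model = PotentialModel.from_debye_length(1000.0, 10.0, 50.0)
        assert hmin_over_href(model, 1e-9, env) == pytest.approx(1.0, abs=1e-3)

    def test_monotone_in_force_and_amplitude(self, env):
        lam = 1 / 200.0
        ratios_f = [
            hmin_over_href(PotentialModel.from_debye_length(1000.0, 10.0, f), lam, env)
            for f in (40.0, 50.0, 60.0, 80.0)
        ]
        assert np.all(np.diff(ratios_f) > 0)
        ratios_b = [
            hmin_over_href(PotentialModel.from_debye_length(b, 10.0, 50.0), lam, env)
            for b in (500.0, 1000.0, 2000.0, 4000.0)
        ]
        assert np.all(np.diff(ratios_b) > 0)
        assert max(ratios_f + ratios_b) <= 1.0

    def test_undefined_when_optical_weight_exceeds_gravity(self, env):
        model = PotentialModel.from_debye_length(1000.0, 10.0, 15.0)
        with pytest.raises(ValueError, match="Lambda"):
            hmin_over_href(model, 1 / 200.0, env)  # Lambda*kT ~ 20 fN > 15 fN


class TestDesignHelpers:
    def test_debye_length_values(self):
        assert debye_length_from_salt(1e-3) == pytest.approx(9.6, abs=0.05)
        assert debye_length_from_salt(0.304**2) == pytest.approx(1.0, rel=1e-12)
        assert debye_length_from_salt(0.25e-3) == pytest.approx(19.2, abs=0.1)

    def test_buoyant_weight_of_3um_polystyrene(self, env):
        mass, weight = buoyant_weight(env)
        assert mass == pytest.approx(5.65e-15, rel=0.01)
        assert weight == pytest.approx(55.0, rel=0.02)

    def test_neutrally_buoyant_rejected(self):
        with pytest.raises(ValueError):
            Environment(particle_density=1000.0, solvent_density=1000.0)

    def test_max_sampling_time_at_50nm(self, particle3, env):
        # the design rule: ~0.2 ms at 50 nm for the benchmark bead
        assert max_sampling_time(50.0, particle3, env, dh=0.2) == pytest.approx(
            0.2, abs=0.02
        )

    def test_max_sampling_time_linear_in_resolution(self, particle3, env):
        t1 = max_sampling_time(50.0, particle3, env, dh=0.2)
        t2 = max_sampling_time(50.0, particle3, env, dh=0.4)
        assert t2 == pytest.approx(2 * t1, rel=1e-12)

    def test_unbounded_at_potential_minimum(self, particle3, env):
        # the force vanishes at h_min, so the admissible time diverges
        h_min = minimum_position(particle3, env)
        assert max_sampling_time(h_min, particle3, env) > 1e9


class TestStickMobility:
    def test_limits(self, env):
        assert diffusion_stick(0.0, env) == 0.0
        assert diffusion_stick(1e9, env) == pytest.approx(env.bulk_diffusion, rel=1e-3)

    def test_value_at_h_equals_radius(self, env):
        # (6 + 2)/(6 + 9 + 2) = 8/17 of the bulk value
        h_nm = env.particle_radius / 1e-9
        assert diffusion_stick(h_nm, env) == pytest.approx(
            env.bulk_diffusion * 8 / 17, rel=1e-12
        )

    def test_monotone_and_bounded(self, env):
        h = np.linspace(1.0, 5e4, 2000)
        d = diffusion_stick(h, env)
        assert np.all(np.diff(d) > 0)
        assert np.all(d > 0) and np.all(d < env.bulk_diffusion)

    @given(h=st.floats(1.0, 1e4))
    def test_derivative_matches_finite_difference(self, h):
        env = Environment()
        dh = h * 1e-6
        fd = (diffusion_stick(h + dh, env) - diffusion_stick(h - dh, env)) / (
            2 * dh * 1e-9
        )
        assert diffusion_stick_derivative(h, env) == pytest.approx(fd, rel=1e-6)


class TestSlipMobility:
    def test_table_rows_as_shipped(self):
        row = SlipCoefficients.from_slip_parameter(0.12)
        assert (row.A, row.B, row.C, row.D) == (0.25, 2.20, -2.6414, 4.55)
        row3 = SlipCoefficients.from_slip_parameter(1 / 3)
        assert (row3.B, row3.C, row3.D) == (0.2, 0.708214, 0.033)
        assert all(r.A == 0.25 for r in SLIP_TABLE)

    def test_value_at_small_gap(self, env):
        # eps = 0.01 with zeta = 1/12: friction bracket 25 + 3.5749 ln(100)
        # - 6.2238 + 0.107 ln(100) => D_n/D0 ~ 0.0280
        slip = SlipCoefficients.from_slip_parameter(1 / 12)
        h = 0.01 * env.particle_radius / 1e-9
        ratio = diffusion_slip(h, env, slip) / env.bulk_diffusion
        assert ratio == pytest.approx(0.0280, abs=0.0002)
        # stick is markedly slower at the same gap
        stick_ratio = diffusion_stick(h, env) / env.bulk_diffusion
        assert stick_ratio == pytest.approx(0.00985, abs=0.0001)
        assert ratio > stick_ratio

    def test_slip_exceeds_stick_in_lubrication_regime(self, env):
        h = np.linspace(1.0, 0.1 * env.particle_radius / 1e-9, 200)
        for row in SLIP_TABLE:
            assert np.all(
                np.asarray(diffusion_slip(h, env, row))
                >= np.asarray(diffusion_stick(h, env))
            )

    def test_derivative_matches_finite_difference(self, env):
        slip = SlipCoefficients.from_slip_parameter(1 / 12)
        for h in (10.0, 50.0, 200.0, 600.0):
            dh = h * 1e-6
            fd = (
                diffusion_slip(h + dh, env, slip) - diffusion_slip(h - dh, env, slip)
            ) / (2 * dh * 1e-9)
            assert diffusion_slip_derivative(h, env, slip) == pytest.approx(
                fd, rel=1e-6
            )

    def test_warns_outside_lubrication_regime(self, env):
        slip = SlipCoefficients.from_slip_parameter(1 / 12)
        with pytest.warns(UserWarning, match="lubrication"):
            diffusion_slip(0.5 * env.particle_radius / 1e-9, env, slip)

    def test_slip_length_values(self, env):
        r = env.particle_radius
        assert slip_length(1 / 12, r) == pytest.approx(r / 9, rel=1e-12)
        assert slip_length(0.0, r) == 0.0
        assert np.isinf(slip_length(1 / 3, r))
        with pytest.raises(ValueError):
            slip_length(0.4, r)


class TestDriftVelocity:
    def test_pure_spurious_drift_at_minimum(self, particle3, stick_mobility, env):
        h_min = minimum_position(particle3, env)
        v = drift_velocity_theory(h_min, particle3, stick_mobility)
        assert v == pytest.approx(
            stick_mobility.diffusion_derivative(h_min), rel=1e-9
        )
        assert v > 0

    def test_stokes_settling_far_from_wall(self, particle3, stick_mobility, env):
        # gravity term only: v -> -F_g/(6 pi eta R) ~ -1.13 um/s
        v = drift_velocity_theory(2e6, particle3, stick_mobility)
        v_stokes = -64e-15 / env.stokes_drag
        assert v == pytest.approx(v_stokes, rel=5e-3)
        assert v_stokes == pytest.approx(-1.13e-6, rel=0.01)

    def test_sign_change_across_minimum(self, particle3, stick_mobility, env):
        h_min = minimum_position(particle3, env)
        below = drift_velocity_theory(h_min - 15, particle3, stick_mobility)
        above = drift_velocity_theory(h_min + 40, particle3, stick_mobility)
        assert below > 0 > above
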