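"""Synthetic gait generators: geometry, shooting solve, limits, noise."""

import numpy as np
import pytest

from comwalk import (
    GaitParameters,
    SolverError,
    SyntheticGaitSpec,
    ValidationError,
    add_noise,
    analyze_synthetic,
    gen_level,
    gen_pendular,
    gen_sinusoidal,
    solve_pendular,
)

H = np.sqrt(1.07**2 - 0.385**2)  # switch height for the shared parameters
PHI0 = np.arcsin(0.385 / 1.07)


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"kind": "hopping"},
            {"d": 2.2},             # d >= 2 l0
            {"v0": 0.0},
            {"a": -0.01},
            {"n_steps": 0},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            SyntheticGaitSpec(**kwargs)

    def test_derived_geometry(self):
        spec = SyntheticGaitSpec()
        assert spec.h == pytest.approx(H, rel=1e-12)
        assert spec.phi0 == pytest.approx(PHI0, rel=1e-12)


class TestLevelGait:
    def test_constant_height(self, level_gait):
        np.testing.assert_allclose(level_gait.trajectory.y, H, rtol=1e-12)

    def test_leg_reaches_l0_at_switch(self, level_gait):
        traj = level_gait.trajectory
        for seg in level_gait.segments:
            l_switch = np.hypot(
                traj.x[seg.switch_index] - seg.contact_before, traj.y[seg.switch_index]
            )
            assert l_switch == pytest.approx(1.07, abs=1e-9)

    def test_work_matches_closed_form(self, level_gait, params):
        # analytic positive work per step for constant-height motion
        W_exact = 2 * params.m * params.g * H * np.log(1.07 / H)
        res = analyze_synthetic(level_gait, params)
        assert res.stats["work_pos_J_mean"] == pytest.approx(W_exact, rel=2e-3)

    def test_mean_speed_exact(self, level_gait):
        traj = level_gait.trajectory
        for seg in level_gait.segments:
            v = seg.d / seg.t_step
            assert v == pytest.approx(1.4, abs=1e-9)


class TestSinusoidalGait:
    def test_height_range_and_switch_geometry(self, sinusoidal_gait):
        y = sinusoidal_gait.trajectory.y
        assert y.min() == pytest.approx(H, abs=1e-12)
        assert y.max() == pytest.approx(H + 0.04, abs=1e-12)
        traj = sinusoidal_gait.trajectory
        for seg in sinusoidal_gait.segments:
            l_switch = np.hypot(
                traj.x[seg.switch_index] - seg.contact_before,
                traj.y[seg.switch_index],
            )
            assert l_switch == pytest.approx(1.07, abs=1e-6)

    def test_zero_amplitude_reduces_to_level(self):
        spec_flat = SyntheticGaitSpec(kind="sinusoidal", a=0.0)
        flat = gen_sinusoidal(spec_flat)
        level = gen_level(SyntheticGaitSpec(kind="level"))
        np.testing.assert_array_equal(flat.trajectory.y, level.trajectory.y)
        np.testing.assert_array_equal(flat.trajectory.x, level.trajectory.x)

    def test_small_amplitude_work_approaches_level(self, params):
        tiny = gen_sinusoidal(SyntheticGaitSpec(kind="sinusoidal", a=1e-4))
        W_tiny = analyze_synthetic(tiny, params).stats["work_pos_J_mean"]
        W_level = 2 * params.m * params.g * H * np.log(1.07 / H)
        assert W_tiny == pytest.approx(W_level, rel=1e-2)

    def test_work_matches_reference(self, sinusoidal_gait, params):
        res = analyze_synthetic(sinusoidal_gait, params)
        assert res.stats["work_pos_J_mean"] == pytest.approx(109.15, rel=1e-2)


class TestPendularSolve:
    def test_geometry_and_speeds(self, params):
        sol = solve_pendular(SyntheticGaitSpec(kind="pendular"), params)
        assert sol.phi0 == pytest.approx(PHI0, rel=1e-12)
        assert sol.v_mid == pytest.approx(1.28, abs=0.01)
        assert sol.v_hs == pytest.approx(1.745, abs=0.005)
        assert sol.t_step == pytest.approx(0.55, abs=1e-9)

    def test_energy_conservation_along_arc(self, params):
        sol = solve_pendular(SyntheticGaitSpec(kind="pendular"), params)
        residual = (
            0.5 * sol.v_hs**2
            - 0.5 * sol.v_mid**2
            - params.g * 1.07 * (1 - np.cos(sol.phi0))
        )
        assert abs(residual) < 1e-9

    def test_unreachable_speed_raises(self, params):
        # very slow target: gravity acceleration along the arc forces the
        # average speed above v0 for every midstance speed in the bracket
        spec = SyntheticGaitSpec(kind="pendular", v0=0.2)
        with pytest.raises(SolverError):
            solve_pendular(spec, params)


class TestPendularGait:
    def test_arc_geometry(self, pendular_gait):
        y = pendular_gait.trajectory.y
        assert y.max() == pytest.approx(1.07, abs=1e-9)
        assert y.min() == pytest.approx(1.07 * np.cos(PHI0), abs=1e-6)

    def test_rigid_leg_on_arcs(self, pendular_gait):
        traj = pendular_gait.trajectory
        k = np.round((traj.x - 1.07 * np.sin(0)) / 0.77)  # nearest contact
        l = np.hypot(traj.x - np.clip(k, 0, 5) * 0.77, traj.y)
        # every sample lies on a circle of radius l0 about some contact
        assert np.abs(l - 1.07).max() < 1e-7

    def test_average_speed_is_v0(self, pendular_gait):
        for seg in pendular_gait.segments:
            assert seg.d / seg.t_step == pytest.approx(1.4, abs=1e-6)

    def test_impact_loss_recorded(self, pendular_gait, params):
        # 1/2 m v_hs^2 sin^2(2 phi0) evaluated at the solved heel-strike speed
        sol = pendular_gait.solution
        expected = 0.5 * params.m * sol.v_hs**2 * np.sin(2 * sol.phi0) ** 2
        assert pendular_gait.e_impact == pytest.approx(expected, rel=1e-12)
        assert pendular_gait.e_impact == pytest.approx(64.80, rel=1e-2)


class TestAddNoise:
    def test_zero_sigma_is_identity(self, sinusoidal_gait_200hz):
        traj = sinusoidal_gait_200hz.trajectory
        noisy = add_noise(traj, 0.0, seed=3)
        np.testing.assert_array_equal(noisy.x, traj.x)
        np.testing.assert_array_equal(noisy.y, traj.y)

    def test_fixed_seed_reproducible(self, sinusoidal_gait_200hz):
        traj = sinusoidal_gait_200hz.trajectory
        a = add_noise(traj, 1e-3, seed=42)
        b = add_noise(traj, 1e-3, seed=42)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.y, b.y)

    def test_derivatives_dropped(self, sinusoidal_gait_200hz):
        noisy = add_noise(sinusoidal_gait_200hz.trajectory, 1e-3, seed=0)
        assert not noisy.has_derivatives

    def test_negative_sigma_rejected(self, sinusoidal_gait_200hz):
        with pytest.raises(ValidationError):
            add_noise(sinusoidal_gait_200hz.trajectory, -1e-3, seed=0)


class TestWorkConvergence:
    def test_trapezoid_refinement_second_order(self, params):
        # halving dt should shrink the change in W+ by more than half
        Ws = [
            analyze_synthetic(
                gen_sinusoidal(
                    SyntheticGaitSpec(kind="sinusoidal", n_steps=2, sample_rate=fs)
                ),
                params,
            ).stats["work_pos_J_mean"]
            for fs in (500.0, 1000.0, 2000.0)
        ]
        d1, d2 = abs(Ws[1] - Ws[0]), abs(Ws[2] - Ws[1])
        assert d2 < 0.5 * d1
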