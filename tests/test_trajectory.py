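"""Ball-flight simulation, spin-axis construction and the inverse solver."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from freekick.constants import ARRIVAL_HEIGHT, DUMMY_FLIGHT_TIME, RELEASE_HEIGHT
from freekick.trajectory import (
    AeroParams,
    InvalidGeometryError,
    KickSpec,
    NonArrivingKickError,
    SpinSpec,
    aero_accel,
    build_spin_axis,
    experiment_design,
    simulate,
    solve_kick,
)

ORIGIN = (0.0, RELEASE_HEIGHT, 23.0)


class TestSpinAxis:
    def test_yaw_matches_arrival_geometry(self):
        # arctan(1.5 / 23) = 3.73 degrees towards the arrival side
        axis = build_spin_axis(15.0, ORIGIN, 1.5, 23.0, curve_sign=-1)
        yaw = math.degrees(math.atan2(axis[0], axis[2]))
        assert yaw == pytest.approx(math.degrees(math.atan(1.5 / 23.0)))
        assert round(yaw, 2) == 3.73

    def test_central_arrival_is_tilted_only(self):
        axis = build_spin_axis(15.0, ORIGIN, 0.0, 23.0, curve_sign=0)
        assert axis[0] == pytest.approx(0.0, abs=1e-12)
        assert axis[1] == pytest.approx(math.cos(math.radians(15.0)))
        assert axis[2] == pytest.approx(math.sin(math.radians(15.0)))

    def test_rightward_curve_negates_axis(self):
        left = build_spin_axis(15.0, ORIGIN, 0.5, 23.0, -1)
        right = build_spin_axis(15.0, ORIGIN, 0.5, 23.0, +1)
        assert np.allclose(left, -right)

    def test_zero_distance_rejected(self):
        with pytest.raises(InvalidGeometryError):
            build_spin_axis(15.0, ORIGIN, 1.5, 0.0, -1)

    @settings(derandomize=True, max_examples=50)
    @given(
        tilt=st.floats(0.0, 89.0),
        lateral=st.floats(-3.0, 3.0),
        curve=st.sampled_from([-1, 0, 1]),
    )
    def test_axis_is_always_unit(self, tilt, lateral, curve):
        axis = build_spin_axis(tilt, ORIGIN, lateral, 23.0, curve)
        assert np.linalg.norm(axis) == pytest.approx(1.0, abs=1e-12)


class TestAeroAccel:
    def test_zero_velocity_gives_pure_gravity(self, aero):
        spin = SpinSpec((0.0, 1.0, 0.0), 1800.0)
        acc = aero_accel([0.0, 0.0, 0.0], spin, aero)
        assert np.allclose(acc, [0.0, -9.81, 0.0])

    def test_no_spin_keeps_acceleration_in_velocity_gravity_plane(self, aero):
        v = np.array([3.0, 2.0, -20.0])
        acc = aero_accel(v, SpinSpec(), aero)
        normal = np.cross(v, [0.0, -1.0, 0.0])
        assert abs(np.dot(acc, normal)) < 1e-12

    def test_components_match_direct_formula(self, aero):
        # Independent single-step evaluation of the force law.
        v = np.array([0.0, 5.0, -25.0])
        spin = SpinSpec((0.0, 1.0, 0.0), 1800.0)
        speed = np.linalg.norm(v)
        k = 0.5 * aero.air_density * aero.cross_section / aero.ball_mass
        drag = -k * aero.drag_coefficient * speed * v
        omega = math.radians(1800.0)
        cl = min(aero.lift_slope * omega * aero.radius / speed, aero.lift_max)
        magnus = k * cl * speed * np.cross([0.0, 1.0, 0.0], v)
        expected = np.array([0.0, -aero.gravity, 0.0]) + drag + magnus
        acc = aero_accel(v, spin, aero)
        assert np.allclose(acc, expected, atol=1e-12)


class TestSimulate:
    def test_zero_drag_matches_ballistic_closed_form(self):
        params = AeroParams(drag_coefficient=0.0)
        kick = KickSpec(0.0, ARRIVAL_HEIGHT, 1.0)
        vy = (ARRIVAL_HEIGHT - RELEASE_HEIGHT + 0.5 * 9.81) / 1.0
        traj = simulate([0.0, vy, -23.0], kick, params)
        t = traj.times
        exact = np.column_stack(
            [
                np.zeros_like(t),
                RELEASE_HEIGHT + vy * t - 0.5 * 9.81 * t**2,
                23.0 - 23.0 * t,
            ]
        )
        assert np.abs(traj.positions - exact).max() < 1e-6
        assert traj.crossing_time(0.0) == pytest.approx(1.0, abs=1e-9)

    def test_mirrored_launch_mirrors_the_path(self, aero):
        axis = build_spin_axis(15.0, ORIGIN, 1.0, 23.0, -1)
        spin_l = SpinSpec(tuple(axis), 1800.0)
        mirrored = np.array([axis[0], -axis[1], -axis[2]])
        spin_r = SpinSpec(tuple(mirrored / np.linalg.norm(mirrored)), 1800.0)
        v = np.array([1.3, 7.0, -26.0])
        kick_l = KickSpec(1.0, ARRIVAL_HEIGHT, 1.0, spin_l)
        kick_r = KickSpec(-1.0, ARRIVAL_HEIGHT, 1.0, spin_r)
        tl = simulate(v, kick_l, aero)
        tr = simulate(v * np.array([-1.0, 1.0, 1.0]), kick_r, aero)
        n = min(len(tl.times), len(tr.times))
        flipped = tl.positions[:n] * np.array([-1.0, 1.0, 1.0])
        assert np.abs(flipped - tr.positions[:n]).max() < 1e-9

    def test_step_halving_converges(self, experimental, aero):
        kick = experimental[0]
        coarse = solve_kick(kick, aero, dt=1e-3)
        fine = simulate(coarse.initial_velocity, kick, aero, dt=5e-4)
        tc, xc, yc = coarse.arrival_state()
        tf, xf, yf = fine.arrival_state()
        assert abs(xc - xf) < 1e-4 and abs(yc - yf) < 1e-4

    def test_non_arriving_kick_raises(self, aero):
        kick = KickSpec(0.0, ARRIVAL_HEIGHT, 1.0)
        with pytest.raises(NonArrivingKickError):
            simulate([0.0, 5.0, 2.0], kick, aero)  # kicked away from goal

    def test_samples_are_continuous_and_end_past_goal(self, solved):
        for traj in solved.values():
            steps = np.linalg.norm(np.diff(traj.positions, axis=0), axis=1)
            assert steps.max() < 0.5
            assert traj.positions[-1, 2] <= -2.0
            z = traj.positions[:, 2]
            goalward = z[z > 0]
            assert np.all(np.diff(goalward) < 0)


class TestSolveKick:
    def test_zero_drag_solution_matches_closed_form(self):
        params = AeroParams(drag_coefficient=0.0)
        kick = KickSpec(0.0, ARRIVAL_HEIGHT, 1.0)
        traj = solve_kick(kick, params)
        vy = (ARRIVAL_HEIGHT - RELEASE_HEIGHT + 0.5 * 9.81) / 1.0
        assert traj.initial_velocity == pytest.approx([0.0, vy, -23.0], abs=1e-6)

    def test_opposite_curves_are_mirror_images(self, solved):
        left = solved["exp_T1.0_x-1.50_h1.75_cL"]
        right = solved["exp_T1.0_x+1.50_h1.75_cR"]
        n = min(len(left.times), len(right.times))
        flipped = left.positions[:n] * np.array([-1.0, 1.0, 1.0])
        assert np.abs(flipped - right.positions[:n]).max() < 1e-6

    def test_sideward_deviation_grows_with_flight_time(self, solved):
        # Fixed spin rate: the curve-induced deviation from the no-spin
        # chord accumulates over time, so longer flights deviate more.
        def deviation(traj):
            tc = traj.crossing_time(0.0)
            mask = traj.times <= tc
            x, t = traj.positions[mask, 0], traj.times[mask]
            chord = x[0] + (x[-1] - x[0]) * (t - t[0]) / (t[-1] - t[0])
            return np.abs(x - chord).max()

        for lat in ("-1.50", "+0.00", "+1.50"):
            for c in ("L", "R"):
                short = deviation(solved[f"exp_T1.0_x{lat}_h1.75_c{c}"])
                long = deviation(solved[f"exp_T1.2_x{lat}_h1.75_c{c}"])
                assert long > short


class TestExperimentDesign:
    def test_counts(self, design):
        assert len([k for k in design if k.kind == "experimental"]) == 18
        assert len([k for k in design if k.kind == "dummy"]) == 45

    def test_experimental_conditions(self, experimental):
        assert all(k.arrival_height == ARRIVAL_HEIGHT for k in experimental)
        assert sorted({k.flight_time for k in experimental}) == [1.0, 1.2]
        assert all(
            (k.spin.rate_deg_s == 1800.0) == (k.curve_sign != 0)
            for k in experimental
        )

    def test_dummy_conditions(self, design):
        dummies = [k for k in design if k.kind == "dummy"]
        assert all(k.flight_time == DUMMY_FLIGHT_TIME for k in dummies)
        assert sorted({k.arrival_height for k in dummies}) == [1.75, 2.12, 2.49]
        assert sorted({k.lateral_arrival for k in dummies}) == [
            -1.5, -0.75, 0.0, 0.75, 1.5,
        ]
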