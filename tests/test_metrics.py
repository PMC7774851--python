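"""Kinematic outcome measures: onset, absolute error, touch, early bias."""
import math

import numpy as np
import pytest
from scipy.interpolate import CubicSpline

from freekick.constants import CONTACT_RADIUS, FRAME_DT
from freekick.metrics import (
    OnsetConfig,
    absolute_error,
    aggregate,
    early_bias,
    initiation_time,
    lateral_velocity,
    metrics_table,
    touch_success,
)
from freekick.preprocess import KinematicSeries

CFG = OnsetConfig()


def make_series(n=135, lhand_x=None, rhand_x=None, head_x=None,
                ball=None, times=None, hand_z=0.3, meta=None):
    if times is None:
        times = np.arange(n) * FRAME_DT
    n = len(times)
    if ball is None:
        ball = np.column_stack(
            [np.zeros(n), np.full(n, 1.75), 23.0 - 23.0 * times]
        )

    def hand(x):
        x = np.zeros(n) if x is None else np.asarray(x, dtype=float)
        return np.column_stack([x, np.full(n, 1.75), np.full(n, hand_z)])

    head = np.column_stack(
        [np.zeros(n) if head_x is None else head_x,
         np.full(n, 1.7), np.zeros(n)]
    )
    return KinematicSeries(
        times=times, head=head, lhand=hand(lhand_x), rhand=hand(rhand_x),
        ball=ball, meta=meta or {},
    )


class TestLateralVelocity:
    def test_linear_motion_gives_constant_velocity(self):
        s = make_series(lhand_x=0.5 * np.arange(135) * FRAME_DT)
        v = lateral_velocity(s, "lhand")
        assert np.allclose(v, 0.5, atol=1e-9)

    def test_stationary_channel_gives_zero(self):
        v = lateral_velocity(make_series(), "rhand")
        assert np.allclose(v, 0.0)

    def test_central_differences_exact_for_quadratics(self):
        t = np.arange(135) * FRAME_DT
        v = lateral_velocity(make_series(lhand_x=t**2), "lhand")
        assert np.allclose(v[1:-1], 2 * t[1:-1], atol=1e-9)


class TestInitiation:
    def test_rectangular_velocity_profile_onset(self):
        # |v| = 0 until 0.300 s, then 1 m/s for 400 ms
        t = np.arange(135) * FRAME_DT
        x = np.clip(t - 0.300, 0.0, None) - np.clip(t - 0.700, 0.0, None)
        s = make_series(lhand_x=x)
        trial, left, right = initiation_time(s, CFG, ae_time=1.2)
        assert left == pytest.approx(0.300, abs=1e-9)
        assert trial == left
        assert math.isnan(right)

    def test_short_blip_is_rejected(self):
        # 150 ms of suprathreshold motion never satisfies the 200 ms rule
        t = np.arange(135) * FRAME_DT
        x = np.clip(t - 0.300, 0.0, None) - np.clip(t - 0.450, 0.0, None)
        trial, left, right = initiation_time(make_series(lhand_x=x), CFG, 1.2)
        assert math.isnan(trial)

    def test_translation_equivariance(self):
        t = np.arange(135) * FRAME_DT
        x = np.clip(t - 0.300, 0.0, None) - np.clip(t - 0.700, 0.0, None)
        base, _, _ = initiation_time(make_series(lhand_x=x), CFG, 1.2)
        shifted, _, _ = initiation_time(
            make_series(lhand_x=x, times=t + 3.0), CFG, 4.2
        )
        assert shifted == pytest.approx(base + 3.0, abs=1e-9)

    def test_earlier_hand_defines_trial_onset(self):
        t = np.arange(135) * FRAME_DT
        early = np.clip(t - 0.30, 0.0, None) - np.clip(t - 0.70, 0.0, None)
        late = np.clip(t - 0.50, 0.0, None) - np.clip(t - 0.90, 0.0, None)
        trial, left, right = initiation_time(
            make_series(lhand_x=late, rhand_x=early), CFG, 1.2
        )
        assert trial == pytest.approx(0.30, abs=1e-9)
        assert right < left


class TestAbsoluteError:
    def test_hand_waiting_at_arrival_point_scores_zero(self):
        s = make_series(lhand_x=np.zeros(135))
        ae, effector, crossings = absolute_error(s)
        assert ae == pytest.approx(0.0, abs=1e-9)
        assert effector == "left"
        # crossing: ball front reaches hand depth plane z = 0.3
        expected = (23.0 - 0.3 - CONTACT_RADIUS) / 23.0
        assert crossings["left"] == pytest.approx(expected, abs=2e-5)

    def test_midpoint_wins_between_two_offset_hands(self):
        s = make_series(lhand_x=np.full(135, -0.2), rhand_x=np.full(135, 0.2))
        ae, effector, _ = absolute_error(s)
        assert ae == pytest.approx(0.0, abs=1e-9)
        assert effector == "midpoint"

    def test_equidistant_tie_prefers_left_hand(self):
        # both hands (and midpoint) at the same spot: deterministic tie-break
        s = make_series(lhand_x=np.full(135, 0.1), rhand_x=np.full(135, 0.1))
        _, effector, _ = absolute_error(s)
        assert effector == "left"

    def test_matches_dense_scan_oracle_on_random_cases(self):
        rng = np.random.default_rng(12)
        checked = 0
        for _ in range(25):
            n = 60
            t = np.arange(n) * FRAME_DT
            ball = np.column_stack(
                [
                    rng.uniform(-1, 1) + rng.uniform(-2, 2) * t,
                    1.5 + rng.uniform(-1, 4) * t,
                    8.0 - rng.uniform(14, 24) * t,
                ]
            )
            lx = rng.uniform(-1, 0) + rng.uniform(-1, 1) * t
            rx = rng.uniform(0, 1) + rng.uniform(-1, 1) * t
            s = make_series(n=n, lhand_x=lx, rhand_x=rx, ball=ball, times=t,
                            hand_z=rng.uniform(0.1, 0.5))
            ae, _, _ = absolute_error(s)
            fine = np.arange(t[0], t[-1], 1e-6)
            splines = {
                name: [CubicSpline(t, arr[:, k]) for k in range(3)]
                for name, arr in (
                    ("l", s.lhand), ("r", s.rhand),
                    ("m", 0.5 * (s.lhand + s.rhand)), ("b", ball),
                )
            }
            best = np.inf
            for eff in ("l", "r", "m"):
                gap = (splines["b"][2](fine) - CONTACT_RADIUS
                       - splines[eff][2](fine))
                hit = np.nonzero(gap <= 0)[0]
                if hit.size == 0 or hit[0] == 0:
                    continue
                tc = fine[hit[0]]
                best = min(
                    best,
                    math.hypot(
                        splines["b"][0](tc) - splines[eff][0](tc),
                        splines["b"][1](tc) - splines[eff][1](tc),
                    ),
                )
            if math.isinf(best) or math.isnan(ae):
                assert math.isinf(best) and math.isnan(ae)
                continue
            assert abs(ae - best) < 1e-4
            checked += 1
        assert checked >= 15


class TestTouch:
    def test_far_pass_is_a_miss(self):
        s = make_series(lhand_x=np.full(135, 1.5), rhand_x=np.full(135, 1.8))
        assert not touch_success(s)

    def test_ball_through_palm_centre_is_a_hit(self):
        s = make_series(lhand_x=np.zeros(135))
        assert touch_success(s)

    def test_grazing_pass_one_millimetre_each_side(self):
        # ball directly above the palm: face distance = half thickness + dy
        n = 3
        t = np.arange(n) * FRAME_DT
        for margin, expect in ((-0.001, True), (+0.001, False)):
            gap = 0.035 / 2 + CONTACT_RADIUS + margin
            ball = np.column_stack(
                [np.zeros(n), np.full(n, 1.75), np.full(n, 0.3 + gap)]
            )
            s = make_series(n=n, lhand_x=np.zeros(n), ball=ball, times=t)
            assert touch_success(s) is expect


class TestEarlyBias:
    def test_stationary_head_has_no_bias(self):
        s = make_series()
        assert early_bias(s, t_goal=1.0, sign_mode="curve", curve_sign=-1) == 0.0

    def test_sign_convention_against_leftward_curve(self):
        # +0.10 m rightward head shift against a leftward curve: bias -0.10
        head = np.linspace(0.0, 0.2, 135)
        s = make_series(head_x=head)
        spline = CubicSpline(s.times, head)
        expected = -(float(spline(0.5)) - head[0])
        value = early_bias(s, t_goal=1.0, sign_mode="curve", curve_sign=-1)
        assert value == pytest.approx(expected, abs=1e-12)
        assert value < 0

    def test_probe_outside_record_raises(self):
        with pytest.raises(ValueError):
            early_bias(make_series(), t_goal=0.3, offset=0.5,
                       sign_mode="curve", curve_sign=1)

    def test_offset_robustness_on_clean_pipeline_output(self, clean_qc):
        # 0.4 / 0.5 / 0.6 s probes agree in sign on noise-limited data
        _, included = clean_qc
        curved = [s for s in included if s.meta["curve_sign"] != 0][:40]
        signs = []
        for offset in (0.4, 0.5, 0.6):
            vals = []
            for s in curved:
                zvals = s.ball[:, 2]
                i = np.nonzero(zvals <= 0)[0][0]
                tg = float(np.interp(0.0, [zvals[i], zvals[i - 1]],
                                     [s.times[i], s.times[i - 1]]))
                vals.append(
                    early_bias(s, tg, offset, "curve",
                               curve_sign=s.meta["curve_sign"])
                )
            signs.append(np.sign(np.nanmean(vals)))
        assert signs[0] == signs[1] == signs[2] == 1.0


class TestAggregate:
    def test_congruence_partition(self, clean_qc):
        _, included = clean_qc
        table = metrics_table(included)
        cong = table[(table.lateral_arrival == -1.5) & (table.curve_sign == -1)]
        assert (cong.congruence == "congruent").all()
        incong = table[(table.lateral_arrival == -1.5) & (table.curve_sign == 1)]
        assert (incong.congruence == "incongruent").all()
        central = table[table.lateral_arrival == 0.0]
        assert (central.congruence == "n/a").all()

    def test_success_rate_definition(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "participant": ["p"] * 10,
                "wall": [False] * 5 + [True] * 5,
                "flight_time": [1.0] * 10,
                "lateral_arrival": [1.5] * 10,
                "curve_sign": [0] * 10,
                "congruence": ["n/a"] * 10,
                "initiation": [0.3] * 10,
                "ae": [0.1] * 10,
                "success": [True, True, True, False, False] + [False] * 5,
                "x_early_curve": [np.nan] * 10,
                "x_early_required": [0.0] * 10,
            }
        )
        agg = aggregate(df)
        assert agg["success"].loc["p", "nowall"] == pytest.approx(60.0)
        assert agg["success"].loc["p", "wall"] == pytest.approx(0.0)

    def test_single_trial_cells_equal_the_trial_value(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "participant": ["p", "p"],
                "wall": [False, True],
                "flight_time": [1.0, 1.0],
                "lateral_arrival": [1.5, 1.5],
                "curve_sign": [0, 0],
                "congruence": ["n/a", "n/a"],
                "initiation": [0.30, 0.38],
                "ae": [0.05, 0.09],
                "success": [True, False],
                "x_early_curve": [np.nan, np.nan],
                "x_early_required": [0.01, 0.02],
            }
        )
        agg = aggregate(df)
        assert agg["initiation"].loc["p", "effect"] == pytest.approx(0.08)
        assert agg["ae"].loc["p", "effect"] == pytest.approx(0.04)
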