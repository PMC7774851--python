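"""Per-trial kinematic outcomes and their condition-level aggregation.

The outcome measures:

* **Movement initiation** -- per hand, the onset of the first period of at
  least 200 ms during which the absolute lateral hand velocity exceeds 5 %
  of that hand's maximal absolute lateral velocity between ball-motion
  onset and the first sample after the absolute-error moment; the trial
  value is the earlier hand.
* **Absolute error (AE)** -- for each of three effectors (left hand, right
  hand, their midpoint) the time at which the front of the ball passes the
  effector's depth plane is solved on a 1e-5 s interpolated grid; AE is
  the minimal xy-plane ball-effector distance over the effectors at their
  own crossing times.  "Front of the ball" is the ball centre minus the
  contact radius along the approach direction.  Ties are broken
  deterministically: a single hand beats the midpoint, left beats right.
* **Touch success** -- whether the ball sphere ever intersects a palm
  collider box (recorded collision flags, when present, take precedence).
* **Early movement bias (X_early)** -- lateral head displacement between
  ball-motion onset and 500 ms before the ball centre crosses the goal
  line, signed positive in the curve direction or in the
  required-movement direction depending on the analysis.

Aggregation produces per-participant means per condition cell and the
wall-effect differences consumed by the statistics layer.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .constants import CONTACT_RADIUS, FRAME_DT, PALM_COLLIDER
from .preprocess import KinematicSeries

__all__ = [
    "OnsetConfig",
    "TrialMetrics",
    "lateral_velocity",
    "initiation_time",
    "absolute_error",
    "touch_success",
    "early_bias",
    "compute_trial_metrics",
    "metrics_table",
    "aggregate",
]

AE_STEP = 1e-5  # s, interpolation step for effector crossings


@dataclass(frozen=True)
class OnsetConfig:
    """Movement-initiation detector settings."""

    velocity_threshold_fraction: float = 0.05
    min_epoch: float = 0.200  # s

    def __post_init__(self) -> None:
        if not 0.0 < self.velocity_threshold_fraction < 1.0:
            raise ValueError("velocity_threshold_fraction must be in (0, 1)")
        if self.min_epoch <= 0:
            raise ValueError("min_epoch must be positive")


@dataclass
class TrialMetrics:
    """All outcomes of a single included trial."""

    initiation: float          # s (nan when no hand qualifies)
    initiation_left: float
    initiation_right: float
    ae: float                  # m
    effector: str              # left | right | midpoint
    crossing_times: dict
    success: bool
    x_early_curve: float       # m, positive in curve direction (nan if none)
    x_early_required: float    # m, positive toward the arrival side
    congruence: str            # congruent | incongruent | n/a


def lateral_velocity(series: KinematicSeries, channel: str) -> np.ndarray:
    """Lateral (x) velocity with gradient semantics: central differences in
    the interior, one-sided at the edges."""
    x = getattr(series, channel)[:, 0]
    if x.size < 3:
        raise ValueError("need at least 3 samples for a velocity estimate")
    return np.gradient(x, series.times)


def _first_run_onset(times: np.ndarray, above: np.ndarray,
                     min_epoch: float) -> float:
    """Start time of the first True-run spanning at least ``min_epoch``."""
    n = len(above)
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if times[j] - times[i] >= min_epoch - 1e-9:
                return float(times[i])
            i = j + 1
        else:
            i += 1
    return math.nan


def initiation_time(
    series: KinematicSeries,
    cfg: OnsetConfig,
    ae_time: float,
) -> tuple[float, float, float]:
    """(trial initiation, left-hand onset, right-hand onset), each possibly
    nan when no qualifying movement epoch exists."""
    # Window for the velocity maximum: ball onset up to the first sample
    # after the AE moment.
    idx = np.searchsorted(series.times, ae_time, side="right")
    idx = min(idx, len(series.times) - 1)
    onsets = []
    for channel in ("lhand", "rhand"):
        v = np.abs(lateral_velocity(series, channel))
        vmax = v[: idx + 1].max()
        if vmax <= 0:
            onsets.append(math.nan)
            continue
        thr = cfg.velocity_threshold_fraction * vmax
        onsets.append(_first_run_onset(series.times, v > thr, cfg.min_epoch))
    left, right = onsets
    if math.isnan(left) and math.isnan(right):
        trial = math.nan
    else:
        trial = np.nanmin([left, right])
    return float(trial), float(left), float(right)


def _crossing_on_fine_grid(ball_z: CubicSpline, eff_z: CubicSpline,
                           t_lo: float, t_hi: float,
                           radius: float) -> float | None:
    """First time in [t_lo, t_hi] at which the ball front reaches the
    effector depth, located on a 1e-5 s grid."""
    fine = np.arange(t_lo, t_hi + AE_STEP, AE_STEP)
    gap = (ball_z(fine) - radius) - eff_z(fine)
    hit = np.nonzero(gap <= 0.0)[0]
    if hit.size == 0:
        return None
    return float(fine[hit[0]])


def absolute_error(
    series: KinematicSeries,
    ball_radius: float = CONTACT_RADIUS,
) -> tuple[float, str, dict]:
    """Minimal xy distance between ball and closest effector at the moment
    the ball front passes that effector's depth plane.

    Returns (AE, winning effector, crossing times per effector).  AE is
    nan when no effector is ever passed.
    """
    t = series.times
    splines = {}
    for name, arr in (("lhand", series.lhand), ("rhand", series.rhand)):
        splines[name] = [CubicSpline(t, arr[:, k]) for k in range(3)]
    mid = 0.5 * (series.lhand + series.rhand)
    splines["midpoint"] = [CubicSpline(t, mid[:, k]) for k in range(3)]
    ball = [CubicSpline(t, series.ball[:, k]) for k in range(3)]

    crossing: dict[str, float] = {}
    best = (math.inf, "")
    for name in ("left", "right", "midpoint"):
        key = {"left": "lhand", "right": "rhand", "midpoint": "midpoint"}[name]
        eff = splines[key]
        gap = (series.ball[:, 2] - ball_radius) - (
            series.lhand[:, 2] if key == "lhand"
            else series.rhand[:, 2] if key == "rhand"
            else mid[:, 2]
        )
        ahead = np.nonzero(gap <= 0.0)[0]
        if ahead.size == 0 or ahead[0] == 0:
            continue  # effector behind the ball start or never crossed
        i = ahead[0]
        tc = _crossing_on_fine_grid(ball[2], eff[2], t[i - 1], t[i], ball_radius)
        if tc is None:
            continue
        crossing[name] = tc
        dx = ball[0](tc) - eff[0](tc)
        dy = ball[1](tc) - eff[1](tc)
        dist = float(np.hypot(dx, dy))
        if dist < best[0]:
            best = (dist, name)
    if not crossing:
        return math.nan, "", {}
    return best[0], best[1], crossing


def _rotation_matrix(euler_deg: np.ndarray) -> np.ndarray:
    """Intrinsic XYZ Euler rotation (degrees); identity for zeros."""
    rx, ry, rz = np.radians(euler_deg)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    mx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    my = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    mz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return mx @ my @ mz


def sphere_box_distance(point: np.ndarray, centre: np.ndarray,
                        rotation: np.ndarray, half_dims: np.ndarray) -> float:
    """Distance from a point to an oriented box (0 inside)."""
    local = rotation.T @ (point - centre)
    d = np.clip(np.abs(local) - half_dims, 0.0, None)
    return float(np.linalg.norm(d))


def touch_success(
    series: KinematicSeries,
    collider_dims=PALM_COLLIDER,
    ball_radius: float = CONTACT_RADIUS,
    hand_rotations: tuple[np.ndarray, np.ndarray] | None = None,
) -> bool:
    """Whether the ball sphere intersects either palm box at any sample."""
    half = np.array(
        [collider_dims[1] / 2.0, collider_dims[0] / 2.0, collider_dims[2] / 2.0]
    )
    n = len(series.times)
    for h, hand in enumerate((series.lhand, series.rhand)):
        rots = hand_rotations[h] if hand_rotations is not None else None
        for i in range(n):
            rot = _rotation_matrix(rots[i]) if rots is not None else np.eye(3)
            if sphere_box_distance(series.ball[i], hand[i], rot, half) <= ball_radius:
                return True
    return False


def early_bias(
    series: KinematicSeries,
    t_goal: float,
    offset: float = 0.5,
    sign_mode: str = "curve",
    curve_sign: int = 0,
    required_sign: float = 0.0,
) -> float:
    """Lateral head displacement at ``t_goal - offset`` relative to onset,
    signed by curve direction or required-movement direction."""
    probe = t_goal - offset
    if probe < series.times[0] or probe > series.times[-1]:
        raise ValueError("bias probe time falls outside the record")
    spline = CubicSpline(series.times, series.head[:, 0])
    disp = float(spline(probe) - series.head[0, 0])
    if sign_mode == "curve":
        if curve_sign == 0:
            return math.nan
        return disp * float(np.sign(curve_sign))
    if sign_mode == "required":
        if required_sign == 0:
            return math.nan
        return disp * float(np.sign(required_sign))
    raise ValueError(f"unknown sign_mode {sign_mode!r}")


def compute_trial_metrics(
    series: KinematicSeries,
    cfg: OnsetConfig | None = None,
    ball_radius: float = CONTACT_RADIUS,
    bias_offset: float = 0.5,
    use_recorded_contact: bool = True,
) -> TrialMetrics:
    cfg = cfg or OnsetConfig()
    ae, effector, crossings = absolute_error(series, ball_radius)
    ae_time = min(crossings.values()) if crossings else series.times[-1]
    if crossings and effector in crossings:
        ae_time = crossings[effector]
    initiation, left, right = initiation_time(series, cfg, ae_time)
    if use_recorded_contact and "contact_recorded" in series.meta:
        success = bool(series.meta["contact_recorded"])
    else:
        success = touch_success(series, ball_radius=ball_radius)
    ball_z = CubicSpline(series.times, series.ball[:, 2])
    # goal-line crossing of the ball centre
    zvals = series.ball[:, 2]
    below = np.nonzero(zvals <= 0.0)[0]
    if below.size and below[0] > 0:
        from scipy.optimize import brentq

        i = below[0]
        t_goal = float(
            brentq(ball_z, series.times[i - 1], series.times[i])
        )
    else:
        t_goal = float(series.times[-1])
    curve = int(series.meta.get("curve_sign", 0))
    lateral = float(series.meta.get("lateral_arrival", 0.0))
    xc = early_bias(series, t_goal, bias_offset, "curve", curve_sign=curve)
    xr = early_bias(series, t_goal, bias_offset, "required",
                    required_sign=lateral)
    if curve == 0 or lateral == 0.0:
        congruence = "n/a"
    elif np.sign(curve) == np.sign(lateral):
        congruence = "congruent"
    else:
        congruence = "incongruent"
    return TrialMetrics(
        initiation=initiation,
        initiation_left=left,
        initiation_right=right,
        ae=ae,
        effector=effector,
        crossing_times=crossings,
        success=success,
        x_early_curve=xc,
        x_early_required=xr,
        congruence=congruence,
    )


def metrics_table(
    included: list[KinematicSeries],
    cfg: OnsetConfig | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Per-trial metrics DataFrame for a set of included series."""
    rows = []
    for series in included:
        tm = compute_trial_metrics(series, cfg, **kwargs)
        meta = series.meta
        rows.append(
            {
                "participant": meta.get("participant"),
                "group": meta.get("group"),
                "trial_index": meta.get("trial_index"),
                "trajectory": meta.get("trajectory"),
                "wall": bool(meta.get("wall")),
                "flight_time": meta.get("flight_time"),
                "lateral_arrival": meta.get("lateral_arrival"),
                "curve_sign": meta.get("curve_sign"),
                "congruence": tm.congruence,
                "initiation": tm.initiation,
                "ae": tm.ae,
                "effector": tm.effector,
                "success": tm.success,
                "x_early_curve": tm.x_early_curve,
                "x_early_required": tm.x_early_required,
                "visible_from": meta.get("visible_from"),
                "t_init_truth": meta.get("t_init_truth"),
            }
        )
    return pd.DataFrame(rows)


def _wall_effect(frame: pd.DataFrame, value: str) -> pd.DataFrame:
    """Per-participant wall / no-wall means and their difference.

    Missing cells (no included trial for a participant x condition) are
    propagated as NaN so the statistics layer can flag them.
    """
    if frame.empty:
        return pd.DataFrame(
            columns=["nowall", "wall", "effect"],
            index=pd.Index([], name="participant"), dtype=float,
        )
    cell = frame.pivot_table(
        index="participant", columns="wall", values=value, aggfunc="mean"
    )
    cell = cell.rename(columns={False: "nowall", True: "wall"})
    for col in ("nowall", "wall"):
        if col not in cell:
            cell[col] = np.nan
    cell["effect"] = cell["wall"] - cell["nowall"]
    return cell[["nowall", "wall", "effect"]]


def aggregate(df: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Condition summaries feeding the statistics layer.

    All summaries are per-participant means over repetitions and the
    averaged-out factors; each frame carries wall/no-wall columns and
    their ``effect`` (wall minus no wall).
    """
    out: dict[str, pd.DataFrame] = {}
    df = df.copy()
    df["success"] = df["success"].astype(float)
    out["initiation"] = _wall_effect(df, "initiation")
    out["ae"] = _wall_effect(df, "ae")
    out["success"] = _wall_effect(df, "success") * 100.0

    for ft, sub in df.groupby("flight_time"):
        out[f"ae_ft{ft:.1f}"] = _wall_effect(sub, "ae")
    short = out.get("ae_ft1.0", _wall_effect(df.iloc[0:0], "ae"))
    long = out.get("ae_ft1.2", _wall_effect(df.iloc[0:0], "ae"))
    out["ae_flight_diff"] = pd.DataFrame(
        {"effect_short": short["effect"], "effect_long": long["effect"]}
    ).assign(diff=lambda d: d.effect_short - d.effect_long)

    outer = df[df["lateral_arrival"].abs() > 0]
    centre = df[df["lateral_arrival"] == 0]
    out["ae_required"] = pd.DataFrame(
        {
            "effect_outer": _wall_effect(outer, "ae")["effect"],
            "effect_centre": _wall_effect(centre, "ae")["effect"],
        }
    ).assign(diff=lambda d: d.effect_outer - d.effect_centre)

    curved = df[df["curve_sign"] != 0]
    straight = df[df["curve_sign"] == 0]
    out["ae_curve"] = pd.DataFrame(
        {
            "effect_curve": _wall_effect(curved, "ae")["effect"],
            "effect_nocurve": _wall_effect(straight, "ae")["effect"],
        }
    ).assign(diff=lambda d: d.effect_curve - d.effect_nocurve)

    out["x_early_curve"] = _wall_effect(curved, "x_early_curve")

    cong = df[df["congruence"] == "congruent"]
    incong = df[df["congruence"] == "incongruent"]
    out["x_early_congruent"] = _wall_effect(cong, "x_early_required")
    out["x_early_incongruent"] = _wall_effect(incong, "x_early_required")
    out["ae_congruence"] = pd.DataFrame(
        {
            "effect_congruent": _wall_effect(cong, "ae")["effect"],
            "effect_incongruent": _wall_effect(incong, "ae")["effect"],
        }
    ).assign(diff=lambda d: d.effect_congruent - d.effect_incongruent)

    # Success-rate cells mirroring the descriptive table: factor x wall.
    cells = []
    for factor, frame, level in (
        ("flight_time", df[df.flight_time == 1.0], "1.0s"),
        ("flight_time", df[df.flight_time == 1.2], "1.2s"),
        ("required", centre, "0m"),
        ("required", outer, "1.5m"),
        ("shape", straight, "no_curve"),
        ("shape", curved, "curve"),
        ("congruence", cong, "congruent"),
        ("congruence", incong, "incongruent"),
    ):
        for wall in (False, True):
            sub = frame[frame.wall == wall]
            rate = (
                sub.groupby("participant")["success"].mean().mean() * 100.0
                if len(sub)
                else np.nan
            )
            cells.append(
                {
                    "factor": factor,
                    "level": level,
                    "wall": wall,
                    "success_rate": rate,
                }
            )
    out["success_table"] = pd.DataFrame(cells)
    return out
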