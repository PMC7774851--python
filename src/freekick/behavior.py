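"""Synthetic goalkeeper sessions with the statistical structure the
analysis assumes.

This module is an explicit generative stand-in for human participants, not
an estimate of human parameters.  Each trial produces a 90 Hz log of head,
hand and ball positions.  The embedded behavioural structure is:

* **Response latency.**  Lateral hand movement starts a normally
  distributed latency after ball release.  When a wall occludes the start
  of the flight, a configurable *fraction* of the occlusion duration is
  added to the initiation time -- the keeper starts later with a wall, but
  by less than the full occlusion (movements begin sooner after the ball
  comes into view).
* **Curve-induced early bias.**  The aimed-at goal-line crossing is the
  true arrival shifted by an over-extrapolation of the visible curvature,
  ``gain * a_lat * (t_goal - t)^2 / 2``; the shift points in the curve
  direction, is largest early in the flight and decays to zero at arrival,
  and is re-evaluated at every replanning interval.
* **Speed-capped reaches.**  Hands move toward the (re-)planned target
  with a smooth velocity ramp capped at ``reach_speed``; a hand that
  cannot cover the distance in time simply arrives late, which is what
  turns a delayed initiation into a larger interception error.
* **Motor noise.**  A per-trial Gaussian aim error; per-participant and
  per-trial latency variation.
* **Tracking artefacts.**  Dropped frames, single-frame hand glitches and
  truncated recordings are injected with known labels so the exclusion
  rules can be validated against ground truth.

Randomness is fully seeded: one master seed is split into per-participant
and per-trial substreams, so any single trial is reproducible in isolation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import CONTACT_RADIUS, FRAME_DT, PALM_COLLIDER
from .trajectory import BallTrajectory

__all__ = [
    "BehaviorParams",
    "CorruptionParams",
    "TrialLog",
    "plan_response",
    "generate_session",
]


@dataclass(frozen=True)
class BehaviorParams:
    """Tunable parameters of the synthetic goalkeeper."""

    base_latency_mean: float = 0.25      # s, lateral response latency
    base_latency_sd: float = 0.03        # s, trial-to-trial
    participant_latency_sd: float = 0.02  # s, between participants
    partial_delay_fraction: float = 0.40  # of the occlusion added when walled
    reach_speed: float = 2.0             # m/s cap on hand speed
    reach_ramp: float = 0.06             # s, smooth velocity onset ramp
    approach_time_constant: float = 0.20  # s, terminal homing on the target
    curve_bias_gain: float = 0.30        # curvature over-extrapolation weight
    replan_interval: float = 0.10        # s between aim updates
    endpoint_noise_sd: float = 0.03      # m, per-trial aim error
    two_hand_offset: float = 0.15        # m between the hands
    head_follow_fraction: float = 0.5    # head translation per hand shift
    hand_height: float = 1.40            # m, start height of the hands
    hand_forward: float = 0.30           # m in front of the face
    eye_height: float = 1.70             # m

    def __post_init__(self) -> None:
        for name in ("base_latency_sd", "participant_latency_sd",
                     "endpoint_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.partial_delay_fraction <= 1.0:
            raise ValueError("partial_delay_fraction must be in [0, 1]")


@dataclass(frozen=True)
class CorruptionParams:
    """Per-trial probabilities of injected tracking artefacts.

    Defaults emulate the exclusion rate seen in motion-tracked goalkeeping
    sessions (roughly 5-7 % of trials affected).
    """

    frame_drop_prob: float = 0.025
    glitch_prob: float = 0.02
    glitch_magnitude: float = 0.05   # m, well past the 25 mm jump rule
    truncate_prob: float = 0.015

    def __post_init__(self) -> None:
        for name in ("frame_drop_prob", "glitch_prob", "truncate_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")


@dataclass
class TrialLog:
    """One trial's raw time series plus metadata.

    Positions are (N, 3) arrays in the analysis frame; orientation channels
    are Euler angles in degrees (identity for the synthetic keeper).
    ``meta`` carries the trial's condition factors, the ground-truth
    initiation time and any injected corruption labels.
    """

    times: np.ndarray
    head: np.ndarray
    head_rot: np.ndarray
    lhand: np.ndarray
    lhand_rot: np.ndarray
    rhand: np.ndarray
    rhand_rot: np.ndarray
    ball: np.ndarray
    contact: np.ndarray
    meta: dict = field(default_factory=dict)

    def n_frames(self) -> int:
        return len(self.times)


def _lateral_curvature(traj: BallTrajectory, t_goal: float) -> float:
    """Signed lateral acceleration of the flight (quadratic fit up to goal)."""
    mask = traj.times <= t_goal
    t = traj.times[mask]
    if t.size < 5:
        return 0.0
    coeffs = np.polyfit(t, traj.positions[mask, 0], 2)
    return 2.0 * float(coeffs[0])


def _palm_contact(ball_xyz: np.ndarray, hand_xyz: np.ndarray,
                  dims=PALM_COLLIDER, radius: float = CONTACT_RADIUS) -> np.ndarray:
    """Vectorised sphere/axis-aligned-palm-box intersection per frame."""
    half = np.array([dims[1] / 2.0, dims[0] / 2.0, dims[2] / 2.0])
    d = np.abs(ball_xyz - hand_xyz) - half
    d = np.clip(d, 0.0, None)
    return np.linalg.norm(d, axis=1) <= radius


def plan_response(
    traj: BallTrajectory,
    visible_from: float,
    params: BehaviorParams,
    rng: np.random.Generator,
    latency: float | None = None,
    times: np.ndarray | None = None,
):
    """Simulate head and hand series for one trial.

    ``visible_from`` is the occlusion duration (0 without a wall); the
    programmed initiation time is ``latency + partial_delay_fraction *
    visible_from``.  Returns ``(series, truth)`` where ``series`` maps
    channel names to arrays on ``times`` (the trajectory's own grid by
    default) and ``truth`` records the programmed onset and aim.
    """
    if not 0.0 <= visible_from <= traj.times[-1]:
        raise ValueError("visible_from must lie within the trajectory span")
    if latency is None:
        latency = max(
            0.05, rng.normal(params.base_latency_mean, params.base_latency_sd)
        )
    t_init = latency + params.partial_delay_fraction * visible_from

    t_goal, x_f, y_f = traj.arrival_state()
    a_lat = _lateral_curvature(traj, t_goal)
    aim_noise = rng.normal(0.0, params.endpoint_noise_sd)

    def aim_at(t: float) -> float:
        tau = max(0.0, t_goal - t)
        bias = params.curve_bias_gain * 0.5 * a_lat * tau * tau
        return float(np.clip(x_f + aim_noise + bias, -3.0, 3.0))

    if times is None:
        times = traj.times
    n = len(times)
    off = params.two_hand_offset / 2.0
    lpos = np.array([-off, params.hand_height])
    rpos = np.array([off, params.hand_height])
    start_mid = 0.0
    lx = np.empty((n, 2))
    rx = np.empty((n, 2))
    target = aim_at(t_init)
    next_replan = t_init + params.replan_interval
    for i, t in enumerate(times):
        if t >= t_init:
            if t >= next_replan and t < t_goal:
                target = aim_at(t)
                next_replan += params.replan_interval
            tau = t - t_init
            if tau < params.reach_ramp:
                env = params.reach_speed * 0.5 * (
                    1.0 - math.cos(math.pi * tau / params.reach_ramp)
                )
            else:
                env = params.reach_speed
            dt = times[i] - times[i - 1] if i > 0 else FRAME_DT
            for pos, sign in ((lpos, -1.0), (rpos, 1.0)):
                tgt = np.array([target + sign * off, y_f])
                delta = tgt - pos
                dist = math.hypot(delta[0], delta[1])
                if dist > 1e-12:
                    vmag = min(env, dist / params.approach_time_constant)
                    step = min(vmag * dt, dist)
                    pos += delta / dist * step
        lx[i] = lpos
        rx[i] = rpos

    lhand = np.column_stack([lx[:, 0], lx[:, 1],
                             np.full(n, params.hand_forward)])
    rhand = np.column_stack([rx[:, 0], rx[:, 1],
                             np.full(n, params.hand_forward)])
    mid = 0.5 * (lx[:, 0] + rx[:, 0])
    head_x = params.head_follow_fraction * (mid - start_mid)
    head = np.column_stack([head_x, np.full(n, params.eye_height),
                            np.zeros(n)])
    series = {"head": head, "lhand": lhand, "rhand": rhand}
    truth = {
        "t_init": t_init,
        "latency": latency,
        "aim_noise": aim_noise,
        "a_lat": a_lat,
        "t_goal": t_goal,
        "x_f": x_f,
    }
    return series, truth


def _corrupt(times, channels, ball, contact, corruption: CorruptionParams,
             rng: np.random.Generator):
    """Inject tracking artefacts; returns the new arrays and label list."""
    codes: list[str] = []
    n = len(times)
    keep = np.ones(n, dtype=bool)
    if rng.random() < corruption.truncate_prob:
        # Cut the record while the ball is still clearly short of two metres
        # past the goal line, so the completeness rule fires.
        candidates = np.nonzero(ball[:, 2] > -1.0)[0]
        lo = max(5, int(0.4 * n))
        hi = int(candidates[-1]) if candidates.size else n - 2
        if hi > lo:
            cut = int(rng.integers(lo, hi))
            keep[cut:] = False
            codes.append("truncate")
    if rng.random() < corruption.frame_drop_prob:
        kept_idx = np.nonzero(keep)[0]
        if kept_idx.size > 4:
            drop = int(rng.choice(kept_idx[1:-1]))
            keep[drop] = False
            codes.append("frame_drop")
    times = times[keep]
    channels = {k: v[keep] for k, v in channels.items()}
    ball = ball[keep]
    contact = contact[keep]
    if rng.random() < corruption.glitch_prob and len(times) > 4:
        i = int(rng.integers(1, len(times) - 1))
        hand = "lhand" if rng.random() < 0.5 else "rhand"
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        channels = dict(channels)
        glitched = channels[hand].copy()
        glitched[i] += corruption.glitch_magnitude * direction
        channels[hand] = glitched
        codes.append("glitch")
    return times, channels, ball, contact, codes


def generate_session(
    trajectories: dict[str, BallTrajectory],
    visibility: dict[str, float],
    behavior: BehaviorParams,
    corruption: CorruptionParams,
    participant_count: int,
    seed,
    experimental_reps: int = 5,
    dummy_reps: int = 2,
    group: str = "naive",
    timestamp_jitter_sd: float = 0.0003,
) -> list[TrialLog]:
    """Generate full sessions for ``participant_count`` synthetic keepers.

    Each participant completes ``experimental_reps`` repetitions of every
    experimental trajectory and ``dummy_reps`` of every dummy trajectory,
    each both with and without a wall, in randomised order (the default
    5/2 repetitions give 180 experimental plus 180 dummy trials).
    ``visibility`` maps trajectory labels to their occlusion durations.
    """
    if isinstance(seed, np.random.SeedSequence):
        master = seed
    else:
        master = np.random.SeedSequence(seed)
    participant_seeds = master.spawn(participant_count)
    logs: list[TrialLog] = []
    labels = list(trajectories)
    for p in range(participant_count):
        pseq = participant_seeds[p]
        prng = np.random.default_rng(pseq)
        base_latency = max(
            0.08,
            prng.normal(behavior.base_latency_mean,
                        behavior.participant_latency_sd),
        )
        plan = [
            (label, wall, rep)
            for label in labels
            for wall in (True, False)
            for rep in range(
                experimental_reps
                if trajectories[label].kick.kind == "experimental"
                else dummy_reps
            )
        ]
        order = prng.permutation(len(plan))
        trial_seeds = pseq.spawn(len(plan))
        pid = f"{group}_{p + 1:02d}"
        for trial_index, j in enumerate(order):
            label, wall, rep = plan[j]
            traj = trajectories[label]
            rng = np.random.default_rng(trial_seeds[j])
            occ = visibility[label] if wall else 0.0
            if not np.isfinite(occ):
                occ = 0.0
            latency = max(
                0.05, rng.normal(base_latency, behavior.base_latency_sd)
            )
            series, truth = plan_response(
                traj, occ, behavior, rng, latency=latency
            )
            n = len(traj.times)
            jitter = np.clip(
                rng.normal(0.0, timestamp_jitter_sd, n), -0.001, 0.001
            )
            jitter[0] = 0.0
            times = traj.times + jitter
            ball = traj.position_at(times)
            contact = (
                _palm_contact(ball, series["lhand"])
                | _palm_contact(ball, series["rhand"])
            )
            times, channels, ball, contact, codes = _corrupt(
                times, series, ball, contact, corruption, rng
            )
            kick = traj.kick
            m = len(times)
            logs.append(
                TrialLog(
                    times=times,
                    head=channels["head"],
                    head_rot=np.zeros((m, 3)),
                    lhand=channels["lhand"],
                    lhand_rot=np.zeros((m, 3)),
                    rhand=channels["rhand"],
                    rhand_rot=np.zeros((m, 3)),
                    ball=ball,
                    contact=contact,
                    meta={
                        "participant": pid,
                        "group": group,
                        "trial_index": trial_index,
                        "trajectory": label,
                        "kind": kick.kind,
                        "wall": wall,
                        "repetition": rep,
                        "flight_time": kick.flight_time,
                        "lateral_arrival": kick.lateral_arrival,
                        "arrival_height": kick.arrival_height,
                        "curve_sign": kick.curve_sign,
                        "spin_rate": kick.spin.rate_deg_s,
                        "visible_from": occ,
                        "t_init_truth": truth["t_init"],
                        "corruption": codes,
                    },
                )
            )
    return logs
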