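"""Defensive-wall geometry and visibility of the ball from the goal.

The wall is modelled as an opaque screen of ``n_players`` defenders
standing shoulder to shoulder on the line between the ball and the goal
centre: a rectangle reaching from the ground up to the shoulder line,
``distance_from_ball`` metres in front of the kick.  The goalkeeper is a
single eye point on the goal line.  The ball counts as visible at the
first instant its *entire* disc clears the shoulder line along the line of
sight, i.e. when the lowest point of the ball's projected disc passes
above the shoulders (or outside the wall's lateral extent).

The true wall distance and defender height of the original scene are not
published; the defaults below (the 9.15 m free-kick distance of the Laws
of the Game and a 1.40 m effective shoulder line -- defenders in a wall
duck slightly) are configurable and yield initial occlusions of roughly
0.15-0.25 s (about 200 ms on average) for the experimental kicks.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import CONTACT_RADIUS, HALF_GOAL_WIDTH

__all__ = ["WallSpec", "Viewpoint", "visibility_onset"]


@dataclass(frozen=True)
class WallSpec:
    """A defensive wall centred on the ball-goal line."""

    present: bool = True
    n_players: int = 5
    distance_from_ball: float = 9.15
    shoulder_height: float = 1.40
    player_width: float = 0.50

    def __post_init__(self) -> None:
        if self.present and self.n_players < 1:
            raise ValueError("a present wall needs at least one player")
        if self.distance_from_ball <= 0 or self.shoulder_height <= 0 \
                or self.player_width <= 0:
            raise ValueError("wall dimensions must be positive")

    @property
    def width(self) -> float:
        return self.n_players * self.player_width


@dataclass(frozen=True)
class Viewpoint:
    """The goalkeeper's eye on the goal line, centre of the goal by default."""

    eye: tuple[float, float, float] = (0.0, 1.70, 0.0)

    def __post_init__(self) -> None:
        if abs(self.eye[0]) > HALF_GOAL_WIDTH:
            raise ValueError("viewpoint must be laterally within the goal mouth")
        object.__setattr__(self, "eye", tuple(float(c) for c in self.eye))


def _clearance(ball: np.ndarray, eye: np.ndarray, wall_z: float,
               half_width: float, shoulder: float, radius: float) -> float:
    """Signed clearance of the ball's lowest visible point over the wall.

    Positive when the sight line from the eye to the lowest point of the
    ball's projected disc passes the wall plane above the shoulders or
    outside the wall laterally; negative while occluded.
    """
    d = ball - eye
    norm = np.linalg.norm(d)
    if norm == 0.0:
        return 1.0
    dhat = d / norm
    down = np.array([0.0, -1.0, 0.0])
    perp = down - np.dot(down, dhat) * dhat
    pnorm = np.linalg.norm(perp)
    low = ball + radius * perp / pnorm if pnorm > 1e-12 else ball
    denom = low[2] - eye[2]
    if denom == 0.0:
        return 1.0
    s = (wall_z - eye[2]) / denom
    if s <= 0.0 or s >= 1.0:
        return 1.0  # wall plane not between eye and ball
    hit = eye + s * (low - eye)
    lateral_clear = abs(hit[0]) - half_width
    height_clear = hit[1] - shoulder
    return max(lateral_clear, height_clear)


def visibility_onset(
    traj,
    wall: WallSpec,
    view: Viewpoint | None = None,
    ball_radius: float = CONTACT_RADIUS,
    dt: float = 1.0 / 900.0,
) -> float:
    """Time at which the whole ball first clears the defenders' shoulders.

    Returns 0 when no wall is present, and ``nan`` (a flag, not an error)
    when the ball never clears the shoulder line while behind the wall
    plane -- e.g. for an absurdly tall wall.
    """
    if not wall.present:
        return 0.0
    view = view or Viewpoint()
    eye = np.asarray(view.eye, dtype=float)
    wall_z = traj.kick.origin[2] - wall.distance_from_ball
    half_width = wall.width / 2.0

    # March a dense grid while the ball is behind the wall plane.
    t_hi = traj.times[-1]
    try:
        t_pass = traj.crossing_time(wall_z)
    except Exception:
        t_pass = t_hi
    ts = np.arange(0.0, t_pass, dt)
    prev_t = None
    for t in ts:
        c = _clearance(traj.position_at(t), eye, wall_z, half_width,
                       wall.shoulder_height, ball_radius)
        if c > 0.0:
            if prev_t is None:
                return float(t)
            # Bisect the clearance root between the last occluded sample
            # and this one for a sub-sample onset.
            lo, hi = prev_t, float(t)
            for _ in range(40):
                mid = 0.5 * (lo + hi)
                if _clearance(traj.position_at(mid), eye, wall_z, half_width,
                              wall.shoulder_height, ball_radius) > 0.0:
                    hi = mid
                else:
                    lo = mid
            return hi
        prev_t = float(t)
    return math.nan
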