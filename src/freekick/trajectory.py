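"""Spin-influenced ball flight and the inverse free-kick problem.

A free kick is simulated as a point-mass ball under gravity, quadratic
drag and a Magnus force generated by a fixed spin.  The drag acceleration
is ``-(rho*Cd*A / 2m) |v| v`` and the Magnus acceleration is
``(rho*Cl*A / 2m) |v| (omega_hat x v)``, with the lift coefficient ``Cl``
proportional to the spin ratio ``omega*r/|v|`` and capped.  The kick is
specified by its *arrival constraints* (lateral position and height of the
ball centre as it crosses the goal-line plane, and the flight time), and
the launch velocity satisfying those constraints is found by a shooting
method on the integrated flight.

Trajectories are integrated with a fixed-step classical Runge-Kutta scheme
(1 ms internal step) and resampled onto the 90 Hz frame grid used by the
rest of the pipeline; they extend about two metres past the goal line.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq, root

from .constants import (
    ARRIVAL_HEIGHT,
    DUMMY_ARRIVAL_HEIGHTS,
    DUMMY_FLIGHT_TIME,
    DUMMY_LATERAL_ARRIVALS,
    END_MARGIN,
    FLIGHT_TIMES,
    FRAME_RATE,
    GOAL_HEIGHT,
    HALF_GOAL_WIDTH,
    KICK_DISTANCE,
    LATERAL_ARRIVALS,
    RELEASE_HEIGHT,
    SPIN_RATE_DUMMY,
    SPIN_RATE_EXPERIMENTAL,
    SPIN_TILT_DEG,
)

__all__ = [
    "AeroParams",
    "SpinSpec",
    "KickSpec",
    "BallTrajectory",
    "InvalidGeometryError",
    "NonArrivingKickError",
    "UnreachableKickError",
    "build_spin_axis",
    "aero_accel",
    "simulate",
    "solve_kick",
    "experiment_design",
]


class InvalidGeometryError(ValueError):
    """Raised when a geometric construction is degenerate (e.g. zero distance)."""


class NonArrivingKickError(RuntimeError):
    """Raised when an integrated trajectory never reaches the goal line."""


class UnreachableKickError(RuntimeError):
    """Raised when the shooting solver cannot satisfy the arrival constraints."""

    def __init__(self, kick: "KickSpec", residual: np.ndarray):
        self.kick = kick
        self.residual = np.asarray(residual, dtype=float)
        super().__init__(
            f"kick {kick.label!r} did not converge; position residual "
            f"{self.residual} m"
        )


@dataclass(frozen=True)
class AeroParams:
    """Aerodynamic and gravitational parameters of the simulated ball.

    The lift (Magnus) coefficient follows ``Cl = min(lift_slope * S,
    lift_max)`` where ``S = omega * r / |v|`` is the spin ratio; it is zero
    for a non-spinning ball.
    """

    ball_mass: float = 0.430          # kg
    aero_diameter: float = 0.22       # m
    air_density: float = 1.225        # kg/m^3
    drag_coefficient: float = 0.25
    lift_slope: float = 1.0
    lift_max: float = 0.35
    gravity: float = 9.81             # m/s^2, acting along -y

    def __post_init__(self) -> None:
        for name in (
            "ball_mass",
            "aero_diameter",
            "air_density",
            "gravity",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.drag_coefficient < 0 or self.lift_slope < 0 or self.lift_max < 0:
            raise ValueError("aerodynamic coefficients must be non-negative")

    @property
    def radius(self) -> float:
        return self.aero_diameter / 2.0

    @property
    def cross_section(self) -> float:
        return math.pi * self.radius**2

    def lift_coefficient(self, spin_ratio: float) -> float:
        return min(self.lift_slope * spin_ratio, self.lift_max)


@dataclass(frozen=True)
class SpinSpec:
    """A fixed rotation: unit spin axis and rate in deg/s."""

    axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    rate_deg_s: float = 0.0

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
            raise ValueError("spin axis must be a unit vector")
        if self.rate_deg_s < 0:
            raise ValueError("spin rate must be non-negative")
        object.__setattr__(self, "axis", tuple(float(a) for a in axis))

    def omega(self) -> np.ndarray:
        """Angular velocity vector in rad/s."""
        return math.radians(self.rate_deg_s) * np.asarray(self.axis)


@dataclass(frozen=True)
class KickSpec:
    """Arrival constraints of a free kick plus its spin.

    ``lateral_arrival`` and ``arrival_height`` locate the ball centre as it
    crosses the goal-line plane ``z = 0``; ``flight_time`` is the duration
    from release to that crossing.
    """

    lateral_arrival: float
    arrival_height: float
    flight_time: float
    spin: SpinSpec = SpinSpec()
    origin: tuple[float, float, float] = (0.0, RELEASE_HEIGHT, KICK_DISTANCE)
    curve_sign: int = 0
    kind: str = "experimental"
    label: str = ""

    def __post_init__(self) -> None:
        if self.flight_time <= 0:
            raise ValueError("flight_time must be positive")
        if abs(self.lateral_arrival) >= HALF_GOAL_WIDTH:
            raise ValueError("lateral arrival must be inside the goal mouth")
        if not 0.0 < self.arrival_height <= GOAL_HEIGHT + 0.1:
            raise ValueError("arrival height must be within the goal mouth")
        object.__setattr__(self, "origin", tuple(float(c) for c in self.origin))


def build_spin_axis(
    tilt_deg: float,
    origin,
    lateral_arrival: float,
    distance: float,
    curve_sign: int,
) -> np.ndarray:
    """Construct the unit spin axis of a curved free kick.

    A vertical axis is tilted ``tilt_deg`` away from the goal about the
    x-axis, then yawed about the vertical towards the final lateral ball
    position by ``arctan(lateral_arrival / distance)``.  ``curve_sign`` is
    -1 for leftward curve (counter-clockwise spin seen from above, i.e. an
    upward axis), +1 for rightward curve (axis negated) and 0 for no curve
    (tilted axis returned unchanged; the spin rate is zero anyway).
    """
    if distance <= 0:
        raise InvalidGeometryError("distance from goal must be positive")
    if not 0.0 <= tilt_deg < 90.0:
        raise InvalidGeometryError("tilt must be in [0, 90) degrees")
    tilt = math.radians(tilt_deg)
    yaw = math.atan2(lateral_arrival, distance)
    s, c = math.sin(tilt), math.cos(tilt)
    axis = np.array([s * math.sin(yaw), c, s * math.cos(yaw)])
    if curve_sign > 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def aero_accel(velocity, spin: SpinSpec, params: AeroParams) -> np.ndarray:
    """Total acceleration (gravity + drag + Magnus) at one flight state."""
    v = np.asarray(velocity, dtype=float)
    acc = np.array([0.0, -params.gravity, 0.0])
    speed = float(np.linalg.norm(v))
    if speed == 0.0:
        return acc
    k = 0.5 * params.air_density * params.cross_section / params.ball_mass
    acc -= k * params.drag_coefficient * speed * v
    omega = spin.omega()
    w = float(np.linalg.norm(omega))
    if w > 0.0:
        cl = params.lift_coefficient(w * params.radius / speed)
        acc += k * cl * speed * np.cross(omega / w, v)
    return acc


def _integrate(p0, v0, omega, params: AeroParams, *, t_end=None, z_stop=None,
               dt: float = 1e-3, t_max: float = 5.0):
    """Fixed-step RK4 flight integration (scalar inner loop for speed).

    Either integrates exactly to ``t_end`` (the step is adjusted so it
    divides the interval) or until the ball's z-coordinate falls below
    ``z_stop``.  Returns (times, positions, final_velocity).
    """
    m = params.ball_mass
    g = params.gravity
    area = params.cross_section
    kd = 0.5 * params.air_density * params.drag_coefficient * area / m
    km = 0.5 * params.air_density * area / m
    r = params.radius
    slope = params.lift_slope
    clmax = params.lift_max
    wx, wy, wz = (float(w) for w in omega)
    w = math.sqrt(wx * wx + wy * wy + wz * wz)
    if w > 0.0:
        ux, uy, uz = wx / w, wy / w, wz / w
    else:
        ux = uy = uz = 0.0
    wr = w * r

    def acc(vx, vy, vz):
        s2 = vx * vx + vy * vy + vz * vz
        if s2 == 0.0:
            return 0.0, -g, 0.0
        sp = math.sqrt(s2)
        d = -kd * sp
        ax = d * vx
        ay = d * vy - g
        az = d * vz
        if w > 0.0:
            cl = slope * wr / sp
            if cl > clmax:
                cl = clmax
            c = km * cl * sp
            ax += c * (uy * vz - uz * vy)
            ay += c * (uz * vx - ux * vz)
            az += c * (ux * vy - uy * vx)
        return ax, ay, az

    px, py, pz = (float(c) for c in p0)
    vx, vy, vz = (float(c) for c in v0)
    if t_end is not None:
        n_steps = max(1, round(t_end / dt))
        h = t_end / n_steps
    else:
        n_steps = int(math.ceil(t_max / dt))
        h = dt

    times = [0.0]
    xs = [px]
    ys = [py]
    zs = [pz]
    t = 0.0
    h2 = 0.0  # placeholder, set in loop
    for i in range(n_steps):
        h2 = h * 0.5
        a1x, a1y, a1z = acc(vx, vy, vz)
        v2x, v2y, v2z = vx + h2 * a1x, vy + h2 * a1y, vz + h2 * a1z
        a2x, a2y, a2z = acc(v2x, v2y, v2z)
        v3x, v3y, v3z = vx + h2 * a2x, vy + h2 * a2y, vz + h2 * a2z
        a3x, a3y, a3z = acc(v3x, v3y, v3z)
        v4x, v4y, v4z = vx + h * a3x, vy + h * a3y, vz + h * a3z
        a4x, a4y, a4z = acc(v4x, v4y, v4z)
        px += h * (vx + 2.0 * (v2x + v3x) + v4x) / 6.0
        py += h * (vy + 2.0 * (v2y + v3y) + v4y) / 6.0
        pz += h * (vz + 2.0 * (v2z + v3z) + v4z) / 6.0
        vx += h * (a1x + 2.0 * (a2x + a3x) + a4x) / 6.0
        vy += h * (a1y + 2.0 * (a2y + a3y) + a4y) / 6.0
        vz += h * (a1z + 2.0 * (a2z + a3z) + a4z) / 6.0
        t = (i + 1) * h
        times.append(t)
        xs.append(px)
        ys.append(py)
        zs.append(pz)
        if z_stop is not None and pz <= z_stop:
            break

    pos = np.column_stack([xs, ys, zs])
    return np.asarray(times), pos, np.array([vx, vy, vz])


@dataclass
class BallTrajectory:
    """A ball path uniformly sampled on the 90 Hz frame grid.

    The last sample lies at least ``END_MARGIN`` metres past the goal line.
    """

    times: np.ndarray
    positions: np.ndarray
    spin: SpinSpec
    kick: KickSpec
    initial_velocity: np.ndarray | None = None
    _splines: tuple = field(default=None, repr=False, compare=False)

    def _spline(self, axis: int) -> CubicSpline:
        if self._splines is None:
            self._splines = tuple(
                CubicSpline(self.times, self.positions[:, k]) for k in range(3)
            )
        return self._splines[axis]

    def position_at(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.stack([self._spline(k)(t) for k in range(3)], axis=-1)
        return out

    def crossing_time(self, z_plane: float = 0.0) -> float:
        """Time at which the ball centre crosses the given z-plane."""
        z = self.positions[:, 2]
        below = np.nonzero(z <= z_plane)[0]
        if below.size == 0:
            raise NonArrivingKickError(
                f"trajectory never reaches z = {z_plane:.3f} m"
            )
        i = below[0]
        if i == 0:
            return float(self.times[0])
        spline = self._spline(2)
        return float(
            brentq(lambda t: spline(t) - z_plane, self.times[i - 1], self.times[i])
        )

    def arrival_state(self) -> tuple[float, float, float]:
        """(crossing time, lateral position, height) at the goal line."""
        t = self.crossing_time(0.0)
        p = self.position_at(t)
        return t, float(p[0]), float(p[1])


def simulate(
    initial_velocity,
    kick: KickSpec,
    params: AeroParams | None = None,
    dt: float = 1e-3,
) -> BallTrajectory:
    """Integrate a kick launched at ``initial_velocity`` and resample to 90 Hz.

    Raises :class:`NonArrivingKickError` if the ball does not reach the goal
    line within five seconds.
    """
    params = params or AeroParams()
    if dt > 1.0 / FRAME_RATE:
        raise ValueError("internal step must not exceed the frame interval")
    omega = kick.spin.omega()
    times, pos, _ = _integrate(
        kick.origin, initial_velocity, omega, params,
        z_stop=-(END_MARGIN + 0.4), dt=dt,
    )
    if pos[-1, 2] > 0.0:
        raise NonArrivingKickError(
            f"kick {kick.label!r} never reached the goal line "
            f"(final z = {pos[-1, 2]:.2f} m)"
        )
    if pos[-1, 2] > -END_MARGIN:
        raise NonArrivingKickError(
            f"kick {kick.label!r} stalls before {END_MARGIN} m past the goal line"
        )
    splines = [CubicSpline(times, pos[:, k]) for k in range(3)]
    # First frame index whose sample is >= END_MARGIN past the goal line.
    t_past = float(
        brentq(lambda t: splines[2](t) + END_MARGIN, times[0], times[-1])
    )
    n_frames = int(math.ceil(t_past * FRAME_RATE))
    while n_frames / FRAME_RATE > times[-1]:
        n_frames -= 1
    grid = np.arange(n_frames + 1) / FRAME_RATE
    sampled = np.column_stack([s(grid) for s in splines])
    return BallTrajectory(
        times=grid,
        positions=sampled,
        spin=kick.spin,
        kick=kick,
        initial_velocity=np.asarray(initial_velocity, dtype=float),
    )


def solve_kick(
    kick: KickSpec,
    params: AeroParams | None = None,
    dt: float = 1e-3,
    position_tol: float = 1e-4,
) -> BallTrajectory:
    """Find the launch velocity meeting the kick's arrival constraints.

    Shooting method: the flight is integrated to exactly ``flight_time`` and
    the launch velocity (3 unknowns) is adjusted with a damped Newton-type
    root finder until the ball centre sits at
    ``(lateral_arrival, arrival_height, 0)``.  The returned trajectory is
    re-simulated from the solved velocity out to two metres past the goal
    line.
    """
    params = params or AeroParams()
    omega = kick.spin.omega()
    T = kick.flight_time
    target = np.array([kick.lateral_arrival, kick.arrival_height, 0.0])
    origin = np.asarray(kick.origin, dtype=float)

    def shoot(v0):
        _, pos, _ = _integrate(origin, v0, omega, params, t_end=T, dt=dt)
        return pos[-1] - target

    # Vacuum solution with a crude drag allowance as the starting point.
    guess = np.array(
        [
            (kick.lateral_arrival - origin[0]) / T,
            (kick.arrival_height - origin[1]) / T + 0.5 * params.gravity * T,
            -(origin[2] / T) * 1.12,
        ]
    )
    sol = root(shoot, guess, method="hybr", options={"xtol": 1e-13})
    residual = shoot(sol.x)
    if np.linalg.norm(residual) > position_tol:
        raise UnreachableKickError(kick, residual)
    traj = simulate(sol.x, kick, params, dt=dt)
    return traj


def _label(kind: str, flight_time: float, lateral: float, curve: int,
           height: float) -> str:
    cname = {-1: "L", 0: "N", 1: "R"}[curve]
    return (
        f"{kind}_T{flight_time:.1f}_x{lateral:+.2f}_h{height:.2f}_c{cname}"
    )


def experiment_design(origin=(0.0, RELEASE_HEIGHT, KICK_DISTANCE)) -> list[KickSpec]:
    """The 63 kicks of one session: 18 experimental plus 45 dummies.

    Experimental kicks cross 3 lateral arrivals x 3 curve directions x 2
    flight times, all entering at 1.75 m with an 1800 deg/s spin when
    curved.  Dummy kicks (flagged ``kind='dummy'`` and never analysed)
    cross 5 lateral arrivals x 3 heights x 3 curves at a 1.1 s flight time
    with 900 deg/s spin.
    """
    distance = float(origin[2])
    specs: list[KickSpec] = []
    for flight_time in FLIGHT_TIMES:
        for lateral in LATERAL_ARRIVALS:
            for curve in (-1, 0, 1):
                axis = build_spin_axis(SPIN_TILT_DEG, origin, lateral, distance, curve)
                rate = SPIN_RATE_EXPERIMENTAL if curve != 0 else 0.0
                specs.append(
                    KickSpec(
                        lateral_arrival=lateral,
                        arrival_height=ARRIVAL_HEIGHT,
                        flight_time=flight_time,
                        spin=SpinSpec(tuple(axis), rate),
                        origin=tuple(origin),
                        curve_sign=curve,
                        kind="experimental",
                        label=_label("exp", flight_time, lateral, curve, ARRIVAL_HEIGHT),
                    )
                )
    for lateral in DUMMY_LATERAL_ARRIVALS:
        for height in DUMMY_ARRIVAL_HEIGHTS:
            for curve in (-1, 0, 1):
                axis = build_spin_axis(SPIN_TILT_DEG, origin, lateral, distance, curve)
                rate = SPIN_RATE_DUMMY if curve != 0 else 0.0
                specs.append(
                    KickSpec(
                        lateral_arrival=lateral,
                        arrival_height=height,
                        flight_time=DUMMY_FLIGHT_TIME,
                        spin=SpinSpec(tuple(axis), rate),
                        origin=tuple(origin),
                        curve_sign=curve,
                        kind="dummy",
                        label=_label("dum", DUMMY_FLIGHT_TIME, lateral, curve, height),
                    )
                )
    return specs
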