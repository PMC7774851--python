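"""Trial exclusion rules, resampling and filtering.

A raw trial is excluded (never repaired) when any of these fire:

* ``frame_interval`` -- an inter-frame interval outside 0.5-1.5 times the
  ideal 1/90 s interval (a missed frame update);
* ``hand_jump`` -- a hand covering more than 25 mm between successive
  frames (temporary tracking loss);
* ``neighbor_ratio`` -- a hand displacement at least five times the mean
  of the preceding and following displacements (an isolated spike);
* ``incomplete`` -- the ball record stopping short of roughly two metres
  past the goal line (a prematurely ended trial).

Included trials are spline-resampled to an exact 90 Hz grid aligned with
the ball-motion-onset sample, and head and hand channels are low-pass
filtered with a 4th-order 10 Hz Butterworth.  The filter is applied
zero-phase (forward-backward, order halved per pass for a net 4th order),
the movement-science norm that avoids biasing onset times; a causal
single-pass mode is available behind a switch.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt, lfilter

from .constants import FRAME_DT, FRAME_RATE
from .behavior import TrialLog

__all__ = [
    "QC_CODES",
    "KinematicSeries",
    "check_frame_intervals",
    "check_hand_jumps",
    "check_complete",
    "qc_codes",
    "resample_and_filter",
    "run_qc",
]

QC_CODES = ("frame_interval", "hand_jump", "neighbor_ratio", "incomplete")

MAX_HAND_STEP = 0.025          # m between successive frames
NEIGHBOR_RATIO = 5.0
COMPLETENESS_TOLERANCE = 0.25  # m short of the simulated end that still passes


@dataclass
class KinematicSeries:
    """A QC-passed trial on an exact 90 Hz grid starting at ball onset.

    Head and hand channels are filtered; the ball channel is left
    untouched (it is the noise-free simulated path).
    """

    times: np.ndarray
    head: np.ndarray
    lhand: np.ndarray
    rhand: np.ndarray
    ball: np.ndarray
    meta: dict = field(default_factory=dict)


def check_frame_intervals(log: TrialLog) -> bool:
    """True when every inter-frame interval is within 0.5-1.5 x (1/90 s)."""
    d = np.diff(log.times)
    if d.size == 0:
        return False
    return bool(np.all((d >= 0.5 * FRAME_DT) & (d <= 1.5 * FRAME_DT)))


def check_hand_jumps(log: TrialLog) -> set[str]:
    """Return the hand-displacement codes that fire (empty set = pass)."""
    codes: set[str] = set()
    for hand in (log.lhand, log.rhand):
        disp = np.linalg.norm(np.diff(hand, axis=0), axis=1)
        if disp.size and disp.max() > MAX_HAND_STEP:
            codes.add("hand_jump")
        if disp.size >= 3:
            mid = disp[1:-1]
            neigh = 0.5 * (disp[:-2] + disp[2:])
            if np.any((mid >= NEIGHBOR_RATIO * neigh) & (mid > 1e-6)):
                codes.add("neighbor_ratio")
    return codes


def check_complete(log: TrialLog, tolerance: float = COMPLETENESS_TOLERANCE) -> bool:
    """True when the ball record extends to about two metres past the goal.

    Simulated flights end two metres past the goal line, so a complete log
    must reach ``z <= -(2 - tolerance)``.
    """
    from .constants import END_MARGIN

    return bool(log.ball[:, 2].min() <= -(END_MARGIN - tolerance))


def qc_codes(log: TrialLog) -> list[str]:
    """All exclusion codes carried by one trial (each rule independent)."""
    codes: list[str] = []
    if not check_frame_intervals(log):
        codes.append("frame_interval")
    jump = check_hand_jumps(log)
    for code in ("hand_jump", "neighbor_ratio"):
        if code in jump:
            codes.append(code)
    if not check_complete(log):
        codes.append("incomplete")
    return codes


def _butter_filter(x: np.ndarray, cutoff: float, fs: float,
                   zero_phase: bool) -> np.ndarray:
    if zero_phase:
        # Order halved per pass; the forward-backward run restores a net
        # 4th-order magnitude response with zero phase lag.
        b, a = butter(2, cutoff, fs=fs)
        return filtfilt(b, a, x, axis=0)
    b, a = butter(4, cutoff, fs=fs)
    return lfilter(b, a, x, axis=0)


def resample_and_filter(
    log: TrialLog,
    cutoff: float = 10.0,
    zero_phase: bool = True,
) -> KinematicSeries:
    """Natural-cubic-spline resample to exactly 90 Hz, then filter.

    The grid starts at the ball-motion-onset sample (the log's first
    frame) and never extrapolates beyond the recorded span.
    """
    t0 = float(log.times[0])
    rel = log.times - t0
    span = float(rel[-1])
    n = int(np.floor(span * FRAME_RATE + 1e-9)) + 1
    grid = np.arange(n) / FRAME_RATE

    def resample(channel: np.ndarray) -> np.ndarray:
        spline = CubicSpline(rel, channel, bc_type="natural")
        return spline(grid)

    head = _butter_filter(resample(log.head), cutoff, FRAME_RATE, zero_phase)
    lhand = _butter_filter(resample(log.lhand), cutoff, FRAME_RATE, zero_phase)
    rhand = _butter_filter(resample(log.rhand), cutoff, FRAME_RATE, zero_phase)
    ball = resample(log.ball)
    meta = dict(log.meta)
    meta["contact_recorded"] = bool(np.any(log.contact))
    return KinematicSeries(
        times=grid, head=head, lhand=lhand, rhand=rhand, ball=ball, meta=meta
    )


def run_qc(
    session: list[TrialLog],
    cutoff: float = 10.0,
    zero_phase: bool = True,
) -> tuple[pd.DataFrame, list[KinematicSeries]]:
    """Apply all exclusion rules to a session and preprocess the survivors.

    Dummy trials are dropped first and never counted.  Returns the QC
    report (one row per experimental trial) and the included, resampled
    and filtered series.  Verdicts are per-trial, so the report does not
    depend on session order.
    """
    rows = []
    included: list[KinematicSeries] = []
    for log in session:
        if log.meta.get("kind") != "experimental":
            continue
        codes = qc_codes(log)
        rows.append(
            {
                "participant": log.meta.get("participant"),
                "trial_index": log.meta.get("trial_index"),
                "trajectory": log.meta.get("trajectory"),
                "wall": log.meta.get("wall"),
                "excluded": bool(codes),
                "codes": "|".join(codes),
                "injected": "|".join(log.meta.get("corruption", [])),
            }
        )
        if not codes:
            included.append(
                resample_and_filter(log, cutoff=cutoff, zero_phase=zero_phase)
            )
    report = pd.DataFrame(
        rows,
        columns=[
            "participant", "trial_index", "trajectory", "wall",
            "excluded", "codes", "injected",
        ],
    )
    return report, included
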