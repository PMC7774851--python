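"""Text file formats: trajectories, trial sequences, trial logs, tables.

Everything on disk is whitespace- or comma-delimited text.  Trajectory
and log files begin with ``# key=value`` header lines carrying the trial
metadata (and, for pipeline outputs, the config hash and master seed for
provenance).  Positions are written with 12 significant digits so a
write-read round trip is lossless to well below 1e-9 m.

Logs recorded in the original engine frame (+x leftward, +z into the
goal) are ingested through the ``unity`` dialect, which flips the x- and
z-axes into the analysis frame (+x rightward from the goalkeeper, +z
toward the pitch) and maps columns through an explicit column map -- the
deposited-data schema is not standardised, so unknown dialects raise
rather than guess.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import TrialLog
from .trajectory import BallTrajectory, KickSpec, SpinSpec

__all__ = [
    "ParseError",
    "DialectError",
    "write_trajectory",
    "read_trajectory",
    "write_trial_sequence",
    "read_trial_sequence",
    "write_trial_log",
    "read_trial_log",
    "UNITY_DEFAULT_COLUMNS",
    "write_table",
    "read_table",
]

FLOAT_FMT = "%.12g"


class ParseError(ValueError):
    """A malformed file row; carries the offending line number."""

    def __init__(self, path, line_no: int, message: str):
        self.path = str(path)
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


class DialectError(ValueError):
    """An unknown or unsupported file dialect."""


def _fmt(x) -> str:
    return FLOAT_FMT % float(x)


def _header_dict(lines: list[str]) -> dict:
    meta: dict = {}
    for line in lines:
        body = line.lstrip("#").strip()
        for token in body.split():
            if "=" not in token:
                continue
            key, _, value = token.partition("=")
            meta[key] = value
    return meta


def _parse_number(s: str, typ=float):
    try:
        return typ(s)
    except ValueError:
        return s


def write_trajectory(traj: BallTrajectory, path, extra_meta: dict | None = None) -> None:
    kick = traj.kick
    meta = {
        "label": kick.label,
        "kind": kick.kind,
        "flight_time": _fmt(kick.flight_time),
        "lateral_arrival": _fmt(kick.lateral_arrival),
        "arrival_height": _fmt(kick.arrival_height),
        "curve_sign": str(kick.curve_sign),
        "spin_rate": _fmt(kick.spin.rate_deg_s),
        "spin_axis": ",".join(_fmt(a) for a in kick.spin.axis),
        "origin": ",".join(_fmt(c) for c in kick.origin),
    }
    if extra_meta:
        meta.update({k: str(v) for k, v in extra_meta.items()})
    with open(path, "w") as fh:
        fh.write("# " + " ".join(f"{k}={v}" for k, v in meta.items()) + "\n")
        fh.write("# t x y z\n")
        for t, (x, y, z) in zip(traj.times, traj.positions):
            fh.write(f"{_fmt(t)} {_fmt(x)} {_fmt(y)} {_fmt(z)}\n")


def read_trajectory(path) -> BallTrajectory:
    header: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                header.append(line)
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(path, line_no, f"expected 4 fields, got {len(parts)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ParseError(path, line_no, str(exc)) from None
    meta = _header_dict(header)
    axis = tuple(float(a) for a in meta.get("spin_axis", "0,1,0").split(","))
    spin = SpinSpec(axis, float(meta.get("spin_rate", 0.0)))
    kick = KickSpec(
        lateral_arrival=float(meta["lateral_arrival"]),
        arrival_height=float(meta["arrival_height"]),
        flight_time=float(meta["flight_time"]),
        spin=spin,
        origin=tuple(float(c) for c in meta.get("origin", "0,0.12235,23").split(",")),
        curve_sign=int(meta.get("curve_sign", 0)),
        kind=meta.get("kind", "experimental"),
        label=meta.get("label", ""),
    )
    data = np.asarray(rows)
    return BallTrajectory(times=data[:, 0], positions=data[:, 1:4],
                          spin=spin, kick=kick)


def write_trial_sequence(rows: list[dict], path, extra_meta: dict | None = None) -> None:
    """One row per trial: index, trajectory file, rotational velocity
    components (deg/s), wall flag, experimental flag."""
    frame = pd.DataFrame(
        rows,
        columns=["trial_index", "trajectory_file", "omega_x", "omega_y",
                 "omega_z", "wall", "experimental"],
    )
    write_table(frame, path, extra_meta or {})


def read_trial_sequence(path) -> pd.DataFrame:
    return read_table(path)


_LOG_COLUMNS = (
    ["t"]
    + [f"{ch}_{ax}" for ch in ("head", "lhand", "rhand") for ax in "xyz"]
    + [f"{ch}_r{ax}" for ch in ("head", "lhand", "rhand") for ax in "xyz"]
    + ["ball_x", "ball_y", "ball_z", "contact"]
)

# The engine's native log columns: x leftward, z into the goal.
UNITY_DEFAULT_COLUMNS = {name: i for i, name in enumerate(_LOG_COLUMNS)}


def write_trial_log(log: TrialLog, path, extra_meta: dict | None = None) -> None:
    meta = dict(log.meta)
    if extra_meta:
        meta.update(extra_meta)
    meta = {k: ("|".join(v) if isinstance(v, list) else v) for k, v in meta.items()}
    with open(path, "w") as fh:
        fh.write("# " + " ".join(f"{k}={v}" for k, v in meta.items() if v != "")
                 + "\n")
        fh.write("# frame=analysis columns=" + ",".join(_LOG_COLUMNS) + "\n")
        for i in range(log.n_frames()):
            fields = (
                [log.times[i]]
                + list(log.head[i]) + list(log.lhand[i]) + list(log.rhand[i])
                + list(log.head_rot[i]) + list(log.lhand_rot[i])
                + list(log.rhand_rot[i])
                + list(log.ball[i])
            )
            fh.write(" ".join(_fmt(v) for v in fields)
                     + f" {int(log.contact[i])}\n")


def _meta_from_header(header: list[str]) -> dict:
    raw = _header_dict(header)
    meta: dict = {}
    for key, value in raw.items():
        if key in ("frame", "columns"):
            continue
        if key in ("wall", "excluded"):
            meta[key] = value in ("True", "true", "1")
        elif key == "corruption":
            meta[key] = [c for c in value.split("|") if c]
        elif key in ("trial_index", "repetition", "curve_sign"):
            try:
                meta[key] = int(value)
            except ValueError:
                meta[key] = value
        else:
            num = _parse_number(value)
            meta[key] = num
    return meta


def read_trial_log(path, dialect: str = "analysis",
                   column_map: dict[str, int] | None = None) -> TrialLog:
    """Read a trial log.

    ``dialect='analysis'`` reads files written by :func:`write_trial_log`.
    ``dialect='unity'`` reads engine-frame files (columns resolved through
    ``column_map``, defaulting to the native layout) and flips the x- and
    z-axes of every position channel into the analysis frame.
    """
    if dialect not in ("analysis", "unity"):
        raise DialectError(f"unknown trial-log dialect {dialect!r}")
    header: list[str] = []
    rows: list[list[float]] = []
    n_cols = None
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                header.append(line)
                continue
            parts = line.split()
            if n_cols is None:
                n_cols = len(parts)
            if len(parts) != n_cols:
                raise ParseError(path, line_no,
                                 f"expected {n_cols} fields, got {len(parts)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ParseError(path, line_no, str(exc)) from None
    if not rows:
        raise ParseError(path, 0, "no data rows")
    data = np.asarray(rows)
    cols = dict(UNITY_DEFAULT_COLUMNS if dialect == "unity" else
                UNITY_DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)

    def chan(prefix: str, rot: bool = False) -> np.ndarray:
        tag = "r" if rot else ""
        idx = [cols[f"{prefix}_{tag}{ax}"] for ax in "xyz"]
        return data[:, idx].copy()

    times = data[:, cols["t"]]
    head, lhand, rhand = chan("head"), chan("lhand"), chan("rhand")
    head_rot, lhand_rot, rhand_rot = (chan(c, rot=True)
                                      for c in ("head", "lhand", "rhand"))
    ball = data[:, [cols["ball_x"], cols["ball_y"], cols["ball_z"]]].copy()
    contact = (data[:, cols["contact"]] != 0) if "contact" in cols else \
        np.zeros(len(times), dtype=bool)
    if dialect == "unity":
        for arr in (head, lhand, rhand, ball):
            arr[:, 0] *= -1.0
            arr[:, 2] *= -1.0
    meta = _meta_from_header(header)
    return TrialLog(times=times, head=head, head_rot=head_rot, lhand=lhand,
                    lhand_rot=lhand_rot, rhand=rhand, rhand_rot=rhand_rot,
                    ball=ball, contact=contact, meta=meta)


def write_table(frame: pd.DataFrame, path, meta: dict) -> None:
    """CSV with a leading ``# key=value`` provenance line."""
    with open(path, "w") as fh:
        if meta:
            fh.write("# " + " ".join(f"{k}={v}" for k, v in meta.items()) + "\n")
        frame.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_table_meta(path) -> dict:
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        return _header_dict([first])
    return {}
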