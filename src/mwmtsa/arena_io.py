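"""Arena geometry, trajectory containers and tracking-export IO.

Coordinates are arena-centred Cartesian centimetres throughout: the reader
re-centres raw tracker output using the configured arena centre, because the
segment features and the interval smoothing both need centre-relative
geometry.  Rows with missing or non-numeric coordinates are dropped (and
counted), not interpolated; optional linear-in-time interpolation is
available via ``ReaderOptions.interpolate``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ArenaGeometry:
    """Circular pool with a submerged circular platform.

    Defaults model the common rat setup: a 200 cm diameter pool with a
    12 cm diameter platform placed mid-quadrant.
    """

    centre: tuple[float, float] = (0.0, 0.0)
    radius: float = 100.0
    platform_centre: tuple[float, float] = (45.0, 45.0)
    platform_radius: float = 6.0

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.platform_radius <= 0:
            raise ValueError("radii must be positive")
        d = float(np.hypot(self.platform_centre[0] - self.centre[0],
                           self.platform_centre[1] - self.centre[1]))
        if d + self.platform_radius > self.radius + 1e-9:
            raise ValueError("platform must lie fully inside the arena")

    @property
    def centre_xy(self) -> np.ndarray:
        return np.asarray(self.centre, dtype=float)

    @property
    def platform_xy(self) -> np.ndarray:
        return np.asarray(self.platform_centre, dtype=float)


@dataclass(frozen=True)
class Point:
    t: float
    x: float
    y: float


class Trajectory:
    """One animal-trial: strictly increasing times and planar positions (cm).

    Positions are stored as contiguous arrays; ``points`` materialises
    :class:`Point` objects on demand.
    """

    __slots__ = ("animal_id", "group", "day", "trial", "t", "xy", "short")

    def __init__(self, animal_id: str, group: str, day: int, trial: int,
                 t: Sequence[float], xy: Sequence[Sequence[float]]):
        self.animal_id = str(animal_id)
        self.group = str(group)
        self.day = int(day)
        self.trial = int(trial)
        self.t = np.asarray(t, dtype=float)
        self.xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        #: set by the segmentation stage when the path is shorter than one segment
        self.short = False
        if self.t.ndim != 1 or len(self.t) != len(self.xy):
            raise ValueError("t and xy must have matching lengths")
        if len(self.t) < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.xy)):
            raise ValueError("non-finite samples in trajectory")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.day < 1 or self.trial < 1:
            raise ValueError("day and trial are 1-based positive integers")

    @property
    def trajectory_id(self) -> str:
        return f"{self.group}_{self.animal_id}_t{self.trial:02d}"

    @property
    def points(self) -> list[Point]:
        return [Point(float(t), float(x), float(y))
                for t, (x, y) in zip(self.t, self.xy)]

    def __len__(self) -> int:
        return len(self.t)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"Trajectory({self.trajectory_id}, n={len(self)}, "
                f"day={self.day})")

    def validate_in_arena(self, arena: ArenaGeometry, tol: float = 0.05) -> int:
        """Count samples beyond ``R*(1+tol)`` of the arena centre."""
        r = np.linalg.norm(self.xy - arena.centre_xy, axis=1)
        return int(np.sum(r > arena.radius * (1.0 + tol)))


@dataclass(frozen=True)
class PathMetrics:
    escape_latency: float   # s
    path_length: float      # cm
    mean_speed: float       # cm/s


@dataclass
class ReaderOptions:
    """Column resolution and parsing options for delimited track exports."""

    time_col: str | int = "t"
    x_col: str | int = "x"
    y_col: str | int = "y"
    trial_col: str | int = "trial"
    animal_col: str | int = "animal"
    group_col: str | int = "group"
    day_col: str | int = "day"
    delimiter: str = ","
    decimal: str = "."
    skip_rows: int = 0
    header: bool = True
    interpolate: bool = False
    arena_tolerance: float = 0.05


def _col(df: pd.DataFrame, key: str | int, what: str) -> pd.Series:
    if isinstance(key, int):
        if key >= df.shape[1]:
            raise ValueError(f"no column index {key} for {what}")
        return df.iloc[:, key]
    if key not in df.columns:
        raise ValueError(f"cannot resolve {what} column {key!r}; "
                         f"available: {list(df.columns)}")
    return df[key]


def read_tracks(path: str | Path, arena: ArenaGeometry,
                options: ReaderOptions | None = None) -> list[Trajectory]:
    """Read a delimited tracking export into per-trial trajectories.

    One :class:`Trajectory` is returned per (animal, trial) pair.  Rows whose
    coordinates fail to parse are dropped with a logged count; positions are
    re-centred on the configured arena centre; samples beyond the arena
    tolerance are flagged in the log but retained.
    """
    opt = options or ReaderOptions()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=opt.delimiter, decimal=opt.decimal,
                     skiprows=opt.skip_rows,
                     header=0 if opt.header else None)
    if df.empty:
        raise ValueError(f"{path}: no data rows")

    t = pd.to_numeric(_col(df, opt.time_col, "time"), errors="coerce")
    x = pd.to_numeric(_col(df, opt.x_col, "x"), errors="coerce")
    y = pd.to_numeric(_col(df, opt.y_col, "y"), errors="coerce")
    meta = pd.DataFrame({
        "t": t, "x": x, "y": y,
        "trial": _col(df, opt.trial_col, "trial"),
        "animal": _col(df, opt.animal_col, "animal").astype(str),
    })
    meta["group"] = (_col(df, opt.group_col, "group").astype(str)
                     if _has(df, opt.group_col) else "default")
    meta["day"] = (pd.to_numeric(_col(df, opt.day_col, "day"), errors="coerce")
                   if _has(df, opt.day_col) else 1)

    bad = meta[["t", "x", "y"]].isna().any(axis=1)
    n_dropped = int(bad.sum())
    if n_dropped:
        log.info("%s: dropped %d rows with missing/non-numeric coordinates",
                 path.name, n_dropped)
    meta = meta[~bad]
    if meta.empty:
        raise ValueError(f"{path}: no usable coordinate rows")

    cx, cy = arena.centre
    out: list[Trajectory] = []
    for (animal, trial), sub in meta.groupby(["animal", "trial"], sort=True):
        sub = sub.sort_values("t")
        if len(sub) < 2:
            raise ValueError(f"{path}: trial {trial} of animal {animal} "
                             f"has fewer than 2 usable samples")
        tt = sub["t"].to_numpy(float)
        xy = np.column_stack([sub["x"].to_numpy(float) - cx,
                              sub["y"].to_numpy(float) - cy])
        if opt.interpolate:
            tt, xy = _interpolate_gaps(tt, xy)
        traj = Trajectory(animal_id=str(animal), group=str(sub["group"].iloc[0]),
                          day=int(sub["day"].iloc[0]), trial=int(trial),
                          t=tt, xy=xy)
        n_out = traj.validate_in_arena(arena, opt.arena_tolerance)
        if n_out:
            log.warning("%s: %d samples beyond arena tolerance",
                        traj.trajectory_id, n_out)
        out.append(traj)
    return out


def _has(df: pd.DataFrame, key: str | int) -> bool:
    return key in df.columns if isinstance(key, str) else key < df.shape[1]


def _interpolate_gaps(t: np.ndarray, xy: np.ndarray):
    """Resample to the median sampling interval, linear in t."""
    dt = float(np.median(np.diff(t)))
    grid = np.arange(t[0], t[-1] + dt / 2, dt)
    out = np.column_stack([np.interp(grid, t, xy[:, 0]),
                           np.interp(grid, t, xy[:, 1])])
    return grid, out


def path_metrics(traj: Trajectory, arena: ArenaGeometry | None = None) -> PathMetrics:
    """Whole-path performance: escape latency, path length, mean speed."""
    elapsed = float(traj.t[-1] - traj.t[0])
    if elapsed <= 0:
        raise ValueError("elapsed time must be positive")
    steps = np.linalg.norm(np.diff(traj.xy, axis=0), axis=1)
    length = float(steps.sum())
    return PathMetrics(escape_latency=elapsed, path_length=length,
                       mean_speed=length / elapsed)


def write_cohort(trajectories: Iterable[Trajectory], path: str | Path,
                 sidecar: str | Path | None = None) -> None:
    """Write trajectories as a single normalised CSV plus a JSON sidecar."""
    path = Path(path)
    frames = []
    meta = []
    for traj in trajectories:
        frames.append(pd.DataFrame({
            "t": traj.t, "x": traj.xy[:, 0], "y": traj.xy[:, 1],
            "trial": traj.trial, "animal": traj.animal_id,
            "group": traj.group, "day": traj.day,
        }))
        meta.append({"animal": traj.animal_id, "group": traj.group,
                     "day": traj.day, "trial": traj.trial,
                     "n_samples": len(traj)})
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.6f")
    if sidecar is not None:
        Path(sidecar).write_text(json.dumps({"trials": meta}, indent=1))
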