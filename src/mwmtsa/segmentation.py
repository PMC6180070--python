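"""Constant-arc-length, overlapping segmentation of swimming paths.

Segment starts are placed every ``segment_length * (1 - overlap)`` cm of arc;
each segment spans ``segment_length`` cm and boundaries snap to the nearest
sample at or beyond the target arc position (segments are true sample runs,
no sub-sample interpolation).  A trailing start that cannot fit a full-length
segment is discarded.  Paths shorter than one segment yield no segments and
are flagged ``short``; downstream they are classified Direct Finding unless a
whole-path label overrides that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mwmtsa.arena_io import Trajectory


@dataclass(frozen=True)
class SegmentationConfig:
    """Segment length is conventionally expressed as a multiple of the arena
    radius R (2R to 3R work for the standard 100 cm-radius maze)."""

    segment_length: float       # cm
    overlap: float = 0.70       # fraction of segment length shared

    def __post_init__(self) -> None:
        if self.segment_length <= 0:
            raise ValueError("segment_length must be positive")
        if not (0.0 <= self.overlap < 1.0):
            raise ValueError("overlap must be in [0, 1)")

    @property
    def step(self) -> float:
        return self.segment_length * (1.0 - self.overlap)


@dataclass(frozen=True)
class Segment:
    """A slice ``[start_index, end_index]`` (inclusive) of one trajectory."""

    trajectory: Trajectory
    ordinal: int
    start_index: int
    end_index: int
    start_arc: float
    end_arc: float
    centre: np.ndarray          # point at half the segment's arc length

    @property
    def arc_length(self) -> float:
        return self.end_arc - self.start_arc

    @property
    def segment_id(self) -> str:
        return f"{self.trajectory.trajectory_id}_s{self.ordinal:03d}"

    @property
    def xy(self) -> np.ndarray:
        return self.trajectory.xy[self.start_index:self.end_index + 1]


class SegmentationResult(list):
    """List of segments for one trajectory, plus the short-path flag."""

    def __init__(self, segments: list[Segment], short: bool):
        super().__init__(segments)
        self.short = short


def cumulative_arc_length(traj: Trajectory) -> np.ndarray:
    """Arc length from sample 0 to each sample; non-decreasing, starts at 0."""
    steps = np.linalg.norm(np.diff(traj.xy, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(steps)])


def segment_trajectory(traj: Trajectory,
                       cfg: SegmentationConfig) -> SegmentationResult:
    cum = cumulative_arc_length(traj)
    total = float(cum[-1])
    length, step = cfg.segment_length, cfg.step
    if total < length:
        traj.short = True
        return SegmentationResult([], short=True)
    traj.short = False

    segments: list[Segment] = []
    ordinal = 0
    eps = 1e-9
    while ordinal * step + length <= total + eps:
        target_start = ordinal * step
        i0 = int(np.searchsorted(cum, target_start - eps, side="left"))
        start_arc = float(cum[i0])
        i1 = int(np.searchsorted(cum, start_arc + length - eps, side="left"))
        i1 = min(i1, len(cum) - 1)
        if i1 <= i0:
            break
        end_arc = float(cum[i1])
        mid = start_arc + (end_arc - start_arc) / 2.0
        ic = int(np.argmin(np.abs(cum[i0:i1 + 1] - mid))) + i0
        segments.append(Segment(trajectory=traj, ordinal=ordinal,
                                start_index=i0, end_index=i1,
                                start_arc=start_arc, end_arc=end_arc,
                                centre=traj.xy[ic].copy()))
        ordinal += 1
    return SegmentationResult(segments, short=False)


def segment_cohort(trajectories, cfg: SegmentationConfig):
    """Segment every trajectory; returns (all segments, short trajectories)."""
    all_segments: list[Segment] = []
    short: list[Trajectory] = []
    for traj in trajectories:
        res = segment_trajectory(traj, cfg)
        if res.short:
            short.append(traj)
        all_segments.extend(res)
    return all_segments, short
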