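"""Gaussian-weighted mapping of segment classes onto the full swimming paths.

Each path is re-divided into consecutive, non-overlapping arc intervals of
length R (the arena radius).  Every classified segment that overlaps an
interval votes for its class with weight w_k * exp(-d^2 / (2 sigma^2)),
where d is the distance between segment centre and interval centre, sigma
defaults to R, and votes below the kernel cutoff exp(-2) (the value
conventionally printed as 0.14, attained at d = 2 sigma) are discarded.
The class weight w_k is the inverse of the class's share of all classified
segments, with the share clipped into [0.01, 0.5] before inversion so rare
classes are boosted but never explosively, then normalised to sum to one.

Trajectories too short to yield a single segment are classified Direct
Finding end to end, unless the user supplied a whole-path label for them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mwmtsa.arena_io import Trajectory
from mwmtsa.segmentation import Segment, cumulative_arc_length
from mwmtsa.strategies import StrategyClass


@dataclass(frozen=True)
class Interval:
    trajectory: Trajectory
    ordinal: int
    start_arc: float
    end_arc: float
    centre: np.ndarray

    @property
    def length(self) -> float:
        return self.end_arc - self.start_arc


@dataclass(frozen=True)
class SmoothingConfig:
    sigma: float = 100.0                       # cm; defaults to R
    kernel_cutoff: float = math.exp(-2.0)      # value at d = 2*sigma
    weight_bounds: tuple[float, float] = (0.01, 0.5)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (0.0 < self.kernel_cutoff < 1.0):
            raise ValueError("kernel_cutoff must be in (0, 1)")
        lo, hi = self.weight_bounds
        if not (0.0 < lo < hi):
            raise ValueError("weight bounds must be ordered and positive")


@dataclass(frozen=True)
class IntervalClassification:
    interval: Interval
    strategy: StrategyClass
    vote_sums: dict[StrategyClass, float] = field(default_factory=dict)


def build_intervals(traj: Trajectory, R: float) -> list[Interval]:
    """Consecutive arc intervals of length R; the remainder stays as a
    shorter final interval."""
    cum = cumulative_arc_length(traj)
    total = float(cum[-1])
    out: list[Interval] = []
    start = 0.0
    ordinal = 0
    eps = 1e-9
    while start < total - eps or ordinal == 0:
        end = min(start + R, total)
        mid = (start + end) / 2.0
        ic = int(np.argmin(np.abs(cum - mid)))
        out.append(Interval(trajectory=traj, ordinal=ordinal,
                            start_arc=start, end_arc=end,
                            centre=traj.xy[ic].copy()))
        ordinal += 1
        start = start + R
    return out


def class_weights(P: dict[StrategyClass, float],
                  bounds: tuple[float, float] = (0.01, 0.5)
                  ) -> dict[StrategyClass, float]:
    """Inverse-share class weights, share clipped into ``bounds``, normalised."""
    lo, hi = bounds
    present = {c: p for c, p in P.items() if p > 0}
    if not present:
        raise ValueError("all class shares are zero")
    raw = {c: 1.0 / min(max(p, lo), hi) for c, p in present.items()}
    total = sum(raw.values())
    return {c: w / total for c, w in raw.items()}


def segment_class_distribution(classes) -> dict[StrategyClass, float]:
    """Share of classified segments per class (UNDEFINED excluded)."""
    counted = [c for c in classes if c is not StrategyClass.UNDEFINED]
    if not counted:
        raise ValueError("no classified segments")
    n = len(counted)
    out: dict[StrategyClass, float] = {}
    for c in counted:
        out[c] = out.get(c, 0.0) + 1.0 / n
    return out


def classify_interval(interval: Interval, segments: list[Segment], classes,
                      cfg: SmoothingConfig,
                      weights: dict[StrategyClass, float]
                      ) -> IntervalClassification:
    """Apply the Gaussian interval vote to one interval.

    Only segments of a defined class whose arc range overlaps the interval
    with nonzero length, and whose kernel value passes the cutoff, vote.
    An empty candidate set or an exact tie leaves the interval UNDEFINED.
    """
    two_s2 = 2.0 * cfg.sigma ** 2
    sums: dict[StrategyClass, float] = {}
    for seg, cls in zip(segments, classes):
        if cls is StrategyClass.UNDEFINED:
            continue
        if seg.start_arc >= interval.end_arc or seg.end_arc <= interval.start_arc:
            continue
        d2 = float(np.sum((seg.centre - interval.centre) ** 2))
        kernel = math.exp(-d2 / two_s2)
        if kernel < cfg.kernel_cutoff:
            continue
        sums[cls] = sums.get(cls, 0.0) + weights.get(cls, 0.0) * kernel
    if not sums:
        return IntervalClassification(interval, StrategyClass.UNDEFINED, {})
    best = max(sums.values())
    winners = [c for c, v in sums.items() if v == best]
    strategy = winners[0] if len(winners) == 1 else StrategyClass.UNDEFINED
    return IntervalClassification(interval, strategy, sums)


def classify_trajectory_intervals(traj: Trajectory, segments: list[Segment],
                                  classes, cfg: SmoothingConfig, weights,
                                  R: float,
                                  whole_path_label: StrategyClass | None = None
                                  ) -> list[IntervalClassification]:
    """Smooth one trajectory's segment classes onto its R-length intervals.

    ``segments``/``classes`` are the cohort-wide lists; only this
    trajectory's segments vote.  Short-flagged trajectories become Direct
    Finding throughout (or the supplied whole-path label).
    """
    intervals = build_intervals(traj, R)
    own = [(s, c) for s, c in zip(segments, classes) if s.trajectory is traj]
    if traj.short or not own:
        label = whole_path_label if whole_path_label is not None else StrategyClass.DF
        return [IntervalClassification(iv, label, {}) for iv in intervals]
    segs = [s for s, _ in own]
    cls = [c for _, c in own]
    return [classify_interval(iv, segs, cls, cfg, weights) for iv in intervals]


def count_transitions(interval_classes) -> int:
    """Adjacent class changes after removing UNDEFINED entries."""
    seq = [c for c in interval_classes if c is not StrategyClass.UNDEFINED]
    return sum(1 for a, b in zip(seq, seq[1:]) if a is not b)


def strategy_profile(classifications_by_traj: dict[Trajectory, list]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per group x trial class percentages, plus per-animal transition counts.

    Returns ``(profile, transitions)``: the profile holds the percentage of
    defined intervals per class for every group/trial cell (UNDEFINED
    intervals are excluded from the denominator and reported in their own
    ``pct_undefined`` column); transitions are per animal and trial.
    """
    prof_rows = []
    trans_rows = []
    for traj, ics in classifications_by_traj.items():
        classes = [ic.strategy for ic in ics]
        defined = [c for c in classes if c is not StrategyClass.UNDEFINED]
        n_undef = len(classes) - len(defined)
        counts = {c: defined.count(c) for c in set(defined)}
        prof_rows.append({
            "group": traj.group, "animal_id": traj.animal_id,
            "trial": traj.trial, "n_intervals": len(classes),
            "n_defined": len(defined), "n_undefined": n_undef,
            **{f"n_{c.value}": counts.get(c, 0)
               for c in StrategyClass if c is not StrategyClass.UNDEFINED},
        })
        trans_rows.append({"group": traj.group, "animal_id": traj.animal_id,
                           "trial": traj.trial,
                           "transitions": count_transitions(classes)})
    per_traj = pd.DataFrame(prof_rows)
    trans = pd.DataFrame(trans_rows)

    class_cols = [f"n_{c.value}" for c in StrategyClass
                  if c is not StrategyClass.UNDEFINED]
    grouped = per_traj.groupby(["group", "trial"], sort=True).sum(numeric_only=True)
    profile = pd.DataFrame(index=grouped.index)
    denom = grouped["n_defined"].replace(0, np.nan)
    for col in class_cols:
        profile[f"pct_{col[2:]}"] = 100.0 * grouped[col] / denom
    profile["pct_undefined"] = 100.0 * grouped["n_undefined"] / grouped["n_intervals"]
    profile = profile.reset_index()
    return profile, trans


def per_animal_measures(classifications_by_traj: dict[Trajectory, list]) -> pd.DataFrame:
    """Tidy per animal-trial measures for the group statistics.

    One row per trajectory with each class's share of defined intervals and
    the transition count; the input of :func:`mwmtsa.stats.group_compare`.
    """
    rows = []
    for traj, ics in classifications_by_traj.items():
        classes = [ic.strategy for ic in ics]
        defined = [c for c in classes if c is not StrategyClass.UNDEFINED]
        n = len(defined)
        row = {"group": traj.group, "animal_id": traj.animal_id,
               "trial": traj.trial,
               "transitions": float(count_transitions(classes))}
        for c in StrategyClass:
            if c is StrategyClass.UNDEFINED:
                continue
            row[c.value] = (defined.count(c) / n) if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
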