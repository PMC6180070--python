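"""Seeded generator of stereotyped Morris Water Maze swimming paths.

Each of the nine behavioural strategies is emulated by a shaped correlated
random walk: wall hugging for thigmotaxis, wall walking with inward
excursions for incursion, waypoint searches of the central region / a small
region / the platform surroundings for scanning, focused search and target
scanning, a noisy circle at the platform-to-wall distance for the chaining
response, a single loop then a straight run for self orienting, a pass
through the platform's proximity followed by departure for scanning
surroundings, and a near-straight run onto the platform for direct finding.

A trial is a concatenation of strategy bouts drawn from the group's mixture
(each bout at least one arena radius of arc, the framework's resolution
floor), released near the wall at a random angle, and ending at platform
contact or the 90 s timeout.  Default kinematics are 25 cm/s sampled at
10 Hz, which give realistic trial path lengths (hundreds to ~2000 cm).
All randomness flows from one master seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mwmtsa.arena_io import ArenaGeometry, Trajectory
from mwmtsa.labelling import LabelRecord
from mwmtsa.segmentation import Segment, cumulative_arc_length
from mwmtsa.strategies import LABELLABLE, StrategyClass

#: Default strategy mixtures for a stressed-like and a control-like cohort.
#: The stressed group leans on low-level strategies (heavy thigmotaxis and
#: incursion); the control group spreads over goal-directed ones.
#: Group contrasts follow a clean benchmark design: a class is either a true
#: null (identical weight in both groups: IC, FS, CR, SO) or clearly
#: different (TT dominates the stressed group; the searching strategies SC,
#: SS, ST and the sink class DF absorb the difference in the control group).
#: Nulls make the class-level false-positive behaviour of the group
#: statistics testable; ambiguous intermediate contrasts would make
#: cross-segmentation consistency a coin flip rather than a property.
DEFAULT_MIXTURES: dict[str, dict[StrategyClass, float]] = {
    "stress": {
        StrategyClass.TT: 0.45, StrategyClass.IC: 0.10, StrategyClass.SC: 0.05,
        StrategyClass.FS: 0.07, StrategyClass.CR: 0.05, StrategyClass.SO: 0.05,
        StrategyClass.SS: 0.07, StrategyClass.ST: 0.05, StrategyClass.DF: 0.11,
    },
    "control": {
        StrategyClass.TT: 0.15, StrategyClass.IC: 0.10, StrategyClass.SC: 0.15,
        StrategyClass.FS: 0.07, StrategyClass.CR: 0.05, StrategyClass.SO: 0.05,
        StrategyClass.SS: 0.15, StrategyClass.ST: 0.12, StrategyClass.DF: 0.16,
    },
}


#: Per-strategy episode (bout) arc-length ranges in arena-radius units.
#: Persistence is strategy dependent: wall hugging runs on for long
#: stretches, searches last a few radii, a self-orienting loop is short by
#: definition, and a direct run lasts only as long as the way to the
#: platform.  All bouts stay above the framework's ~2R resolution floor
#: except the intrinsically short SO loop.
BOUT_ARC_RANGE: dict[StrategyClass, tuple[float, float]] = {
    StrategyClass.TT: (4.0, 10.0),
    StrategyClass.IC: (3.0, 7.0),
    StrategyClass.SC: (3.0, 6.0),
    StrategyClass.FS: (2.5, 5.0),
    StrategyClass.CR: (2.5, 6.0),
    StrategyClass.SO: (1.5, 2.5),
    StrategyClass.SS: (2.5, 5.0),
    StrategyClass.ST: (2.5, 5.0),
    StrategyClass.DF: (2.0, 3.0),
}


@dataclass(frozen=True)
class StrategyParams:
    speed: float = 25.0            # cm/s
    sampling_hz: float = 10.0
    timeout: float = 90.0          # s
    wall_band: float = 0.92        # fraction of R where wall walks sit
    heading_noise: float = 0.35    # rad/step for searching walks

    def __post_init__(self) -> None:
        if self.speed <= 0 or self.sampling_hz <= 0 or self.timeout <= 0:
            raise ValueError("speed, sampling rate and timeout must be positive")

    @property
    def step(self) -> float:
        return self.speed / self.sampling_hz

    @property
    def max_steps(self) -> int:
        return int(round(self.timeout * self.sampling_hz))


@dataclass(frozen=True)
class CohortSpec:
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"stress": 30, "control": 27})
    mixtures: dict[str, dict[StrategyClass, float]] = field(
        default_factory=lambda: {g: dict(m) for g, m in DEFAULT_MIXTURES.items()})
    trials: int = 12
    trials_per_day: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 1:
                raise ValueError(f"group {g} must have at least one animal")
            total = sum(self.mixtures[g].values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"mixture of group {g} sums to {total}, not 1")


def _wrap(a: np.ndarray) -> np.ndarray:
    return np.arctan2(np.sin(a), np.cos(a))


def _confine(xy: np.ndarray, R: float, limit: float = 0.97) -> np.ndarray:
    """Reflect radial overshoot back inside ``limit * R``."""
    r = np.linalg.norm(xy, axis=1)
    over = r > limit * R
    if np.any(over):
        rr = np.where(over, np.maximum(2 * limit * R - r, 0.3 * R), r)
        safe = np.where(r > 1e-12, r, 1.0)
        xy = xy * (rr / safe)[:, None]
    return xy


def _polar_walk(rng, start: np.ndarray, n: int, step: float, R: float,
                r_target: np.ndarray, r_noise: float) -> np.ndarray:
    """Tangential walk whose radius relaxes onto a target profile."""
    r0 = float(np.hypot(*start))
    theta0 = math.atan2(start[1], start[0])
    relax = np.exp(-np.arange(1, n + 1) / 10.0)
    noise = np.cumsum(rng.normal(0.0, r_noise, n))
    noise -= np.linspace(0, noise[-1] if n else 0.0, n)  # keep it a wiggle
    r = r_target + (r0 - r_target[0]) * relax + noise
    r = np.clip(r, 0.05 * R, 0.97 * R)
    dr = np.diff(np.concatenate([[r0], r]))
    tang = np.sqrt(np.maximum(step ** 2 - dr ** 2, (0.3 * step) ** 2))
    direction = rng.choice([-1.0, 1.0])
    dtheta = direction * tang / np.maximum(r, 1e-6) \
        * (1.0 + rng.normal(0.0, 0.08, n))
    theta = theta0 + np.cumsum(dtheta)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _leg(rng, start: np.ndarray, target: np.ndarray, step: float,
         noise_sd: float, n_cap: int) -> np.ndarray:
    """Constant-speed run toward a target with correlated heading noise.

    The bearing is re-aimed every few steps so heading noise wiggles the
    path without steering it off target.
    """
    chunks: list[np.ndarray] = []
    pos = start
    left = n_cap
    m = 8   # steps between re-aims
    while left > 0:
        d = target - pos
        dist = float(np.hypot(*d))
        if dist < step:
            break
        k = min(m, left, max(int(round(dist / step)), 1))
        bearing = math.atan2(d[1], d[0])
        h = bearing + np.cumsum(rng.normal(0.0, noise_sd, k))
        chunk = pos + np.cumsum(
            np.column_stack([step * np.cos(h), step * np.sin(h)]), axis=0)
        chunks.append(chunk)
        pos = chunk[-1]
        left -= k
    if not chunks:   # already at the target: a token two-step shuffle
        jitter = rng.normal(0.0, 0.3 * step, (min(2, n_cap), 2))
        return start + np.cumsum(jitter, axis=0)
    return np.vstack(chunks)


def _waypoint_walk(rng, start: np.ndarray, n: int, step: float,
                   sample_target, noise_sd: float) -> np.ndarray:
    out: list[np.ndarray] = []
    pos = start
    total = 0
    while total < n:
        leg = _leg(rng, pos, sample_target(), step, noise_sd, n - total)
        out.append(leg)
        total += len(leg)
        pos = leg[-1]
    return np.vstack(out)[:n]


def _bout(strategy: StrategyClass, arena: ArenaGeometry,
          params: StrategyParams, rng: np.random.Generator,
          start: np.ndarray, n: int) -> np.ndarray:
    """Positions (n, 2) of one strategy bout, arena-centred, start excluded."""
    R = arena.radius
    step = params.step
    platform = arena.platform_xy - arena.centre_xy
    dp = float(np.hypot(*platform))

    if strategy is StrategyClass.TT:
        target = np.full(n, params.wall_band * R)
        xy = _polar_walk(rng, start, n, step, R, target, r_noise=0.5)
    elif strategy is StrategyClass.IC:
        period = rng.uniform(40, 70)
        phase = rng.uniform(0, math.pi)
        t = np.arange(1, n + 1)
        target = R * (0.90 - 0.38 * np.abs(np.sin(math.pi * t / period + phase)))
        xy = _polar_walk(rng, start, n, step, R, target, r_noise=0.6)
    elif strategy is StrategyClass.CR:
        radius = dp + rng.normal(0.0, 0.04 * R)
        target = np.full(n, radius) + np.cumsum(rng.normal(0, 0.2, n))
        xy = _polar_walk(rng, start, n, step, R, np.clip(target, 0.3 * R, 0.85 * R),
                         r_noise=0.3)
    elif strategy is StrategyClass.SC:
        # random search sweeping the whole central region: long erratic
        # crossings, rapid direction changes, large radial spread
        def sample():
            r = 0.65 * R * math.sqrt(rng.uniform())
            a = rng.uniform(0, 2 * math.pi)
            return np.array([r * math.cos(a), r * math.sin(a)])
        xy = _waypoint_walk(rng, start, n, step, sample, 0.45)
    elif strategy is StrategyClass.FS:
        # active search of one small region: extremely confined, low
        # efficiency, moderate turning
        a = rng.uniform(0, 2 * math.pi)
        rr = rng.uniform(0.15, 0.45) * R
        centre = np.array([rr * math.cos(a), rr * math.sin(a)])

        def sample():
            ang = rng.uniform(0, 2 * math.pi)
            rad = 0.09 * R * math.sqrt(rng.uniform())
            return centre + [rad * math.cos(ang), rad * math.sin(ang)]
        xy = _waypoint_walk(rng, start, n, step, sample, 0.25)
    elif strategy is StrategyClass.ST:
        # confined search hugging the platform position
        def sample():
            ang = rng.uniform(0, 2 * math.pi)
            rad = rng.uniform(1.2, 2.5) * arena.platform_radius
            return platform + [rad * math.cos(ang), rad * math.sin(ang)]
        xy = _waypoint_walk(rng, start, n, step, sample, 0.25)
    elif strategy is StrategyClass.SS:
        # one near-straight pass through the platform's proximity, then a
        # determined departure towards a distant wall point
        ang = rng.uniform(0, 2 * math.pi)
        near = platform + 2.2 * arena.platform_radius * np.array(
            [math.cos(ang), math.sin(ang)])
        away = near - platform
        far_dir = away / max(float(np.hypot(*away)), 1e-9)
        rot = rng.uniform(-0.6, 0.6)
        cr, sr = math.cos(rot), math.sin(rot)
        far_dir = np.array([cr * far_dir[0] - sr * far_dir[1],
                            sr * far_dir[0] + cr * far_dir[1]])
        far = 0.88 * R * far_dir
        first = _leg(rng, start, near, step, 0.06, n)
        if len(first) < n:
            second = _leg(rng, first[-1], far, step, 0.08, n - len(first))
            xy = np.vstack([first, second])[:n]
        else:
            xy = first[:n]
    elif strategy is StrategyClass.SO:
        loop_r = rng.uniform(0.18, 0.28) * R
        direction = rng.choice([-1.0, 1.0])
        h0 = rng.uniform(0, 2 * math.pi)
        centre = start + loop_r * np.array([math.cos(h0 + direction * math.pi / 2),
                                            math.sin(h0 + direction * math.pi / 2)])
        n_loop = min(max(int(round(2 * math.pi * loop_r / step)), 4), n)
        phi0 = math.atan2(start[1] - centre[1], start[0] - centre[0])
        phi = phi0 + direction * step / loop_r * np.arange(1, n_loop + 1)
        loop = centre + loop_r * np.column_stack([np.cos(phi), np.sin(phi)])
        if n_loop < n:
            a = rng.uniform(0, 2 * math.pi)
            target = 0.5 * R * np.array([math.cos(a), math.sin(a)])
            rest = _leg(rng, loop[-1], target, step, 0.12, n - n_loop)
            xy = np.vstack([loop, rest])[:n]
        else:
            xy = loop[:n]
    elif strategy is StrategyClass.DF:
        xy = _leg(rng, start, platform, step, 0.04, n)
        if len(xy) < n:   # keep station on the platform once reached
            xy = np.vstack([xy, np.repeat(xy[-1:], n - len(xy), axis=0)
                            + rng.normal(0, 0.3, (n - len(xy), 2))])
    else:
        raise ValueError(f"unknown strategy {strategy}")
    return _confine(xy, R)


def generate_strategy_path(strategy: StrategyClass, arena: ArenaGeometry,
                           params: StrategyParams | None = None,
                           seed: int = 0, *, duration: float | None = None,
                           animal_id: str = "sim", group: str = "default",
                           day: int = 1, trial: int = 1) -> Trajectory:
    """One single-strategy trajectory, truncated at platform contact."""
    params = params or StrategyParams()
    rng = np.random.default_rng(seed)
    R = arena.radius
    a = rng.uniform(0, 2 * math.pi)
    start = np.array([0.90 * R * math.cos(a), 0.90 * R * math.sin(a)])
    n = int(round((duration or params.timeout) * params.sampling_hz))
    xy = np.vstack([start, _bout(strategy, arena, params, rng, start, n)])
    platform = arena.platform_xy - arena.centre_xy
    hit = np.where(np.linalg.norm(xy - platform, axis=1)
                   <= arena.platform_radius)[0]
    if len(hit) and hit[0] >= 2:
        xy = xy[:hit[0] + 1]
    t = np.arange(len(xy)) / params.sampling_hz
    return Trajectory(animal_id=animal_id, group=group, day=day, trial=trial,
                      t=t, xy=xy + arena.centre_xy)


def generate_cohort(spec: CohortSpec, arena: ArenaGeometry,
                    params: StrategyParams | None = None
                    ) -> tuple[list[Trajectory], pd.DataFrame]:
    """Two-group cohort of bout-structured trials plus its ground truth.

    Returns the trajectories and a table with one row per strategy bout:
    ``trajectory_id, bout, strategy, start_arc, end_arc`` (arc positions in
    cm along the path).  Deterministic under ``spec.seed``.
    """
    params = params or StrategyParams()
    R = arena.radius
    step = params.step
    platform = arena.platform_xy - arena.centre_xy
    trajectories: list[Trajectory] = []
    truth_rows: list[dict] = []

    groups = sorted(spec.group_sizes)
    for gi, group in enumerate(groups):
        mixture = spec.mixtures[group]
        classes = sorted(mixture, key=lambda c: c.value)
        probs = np.array([mixture[c] for c in classes])
        for animal in range(spec.group_sizes[group]):
            animal_id = f"{group}{animal + 1:02d}"
            for trial in range(1, spec.trials + 1):
                rng = np.random.default_rng(
                    np.random.SeedSequence((spec.seed, gi, animal, trial)))
                a = rng.uniform(0, 2 * math.pi)
                pos = np.array([0.90 * R * math.cos(a),
                                0.90 * R * math.sin(a)])
                chunks = [pos[None, :]]
                bounds: list[tuple[int, StrategyClass]] = []
                used = 0
                escaped = False
                while used < params.max_steps and not escaped:
                    strategy = classes[int(rng.choice(len(classes), p=probs))]
                    lo, hi = BOUT_ARC_RANGE[strategy]
                    target_arc = rng.uniform(lo * R, hi * R)
                    n = min(max(int(round(target_arc / step)), 2),
                            params.max_steps - used)
                    xy = _bout(strategy, arena, params, rng, pos, n)
                    hit = np.where(np.linalg.norm(xy - platform, axis=1)
                                   <= arena.platform_radius)[0]
                    if len(hit):
                        xy = xy[:hit[0] + 1]
                        escaped = True
                    chunks.append(xy)
                    used += len(xy)
                    bounds.append((used, strategy))
                    pos = xy[-1]
                xy_all = np.vstack(chunks)
                t = np.arange(len(xy_all)) / params.sampling_hz
                traj = Trajectory(animal_id=animal_id, group=group,
                                  day=(trial - 1) // spec.trials_per_day + 1,
                                  trial=trial, t=t,
                                  xy=xy_all + arena.centre_xy)
                trajectories.append(traj)
                cum = cumulative_arc_length(traj)
                prev = 0
                for b, (end_idx, strategy) in enumerate(bounds):
                    truth_rows.append({
                        "trajectory_id": traj.trajectory_id, "bout": b,
                        "strategy": strategy.value,
                        "start_arc": float(cum[prev]),
                        "end_arc": float(cum[end_idx]),
                    })
                    prev = end_idx
    return trajectories, pd.DataFrame(truth_rows)


class GroundTruth:
    """Arc-indexed view of a cohort's bout table."""

    def __init__(self, truth: pd.DataFrame):
        self._by_traj: dict[str, list[tuple[float, float, StrategyClass]]] = {}
        for row in truth.itertuples():
            self._by_traj.setdefault(row.trajectory_id, []).append(
                (row.start_arc, row.end_arc, StrategyClass(row.strategy)))

    def coverage(self, trajectory_id: str, start_arc: float,
                 end_arc: float) -> dict[StrategyClass, float]:
        """Arc overlap (cm) of each strategy with ``[start_arc, end_arc]``."""
        out: dict[StrategyClass, float] = {}
        for s, e, cls in self._by_traj.get(trajectory_id, ()):
            ov = min(e, end_arc) - max(s, start_arc)
            if ov > 0:
                out[cls] = out.get(cls, 0.0) + ov
        return out

    def majority(self, trajectory_id: str, start_arc: float,
                 end_arc: float) -> StrategyClass | None:
        cov = self.coverage(trajectory_id, start_arc, end_arc)
        if not cov:
            return None
        return max(sorted(cov, key=lambda c: c.value), key=lambda c: cov[c])


def auto_label(segments: list[Segment], truth: pd.DataFrame,
               fraction: float = 0.10, seed: int = 0,
               straddle_share: float = 0.20) -> list[LabelRecord]:
    """Label a stratified sample of segments from the generator ground truth.

    Each sampled segment gets its majority bout class; a second label is
    added when a runner-up class covers at least ``straddle_share`` of the
    segment's arc (mirroring an expert's two-label call on straddlers).
    The sample is stratified over majority classes and sized to exactly
    ``round(fraction * n_segments)``.
    """
    gt = GroundTruth(truth)
    rng = np.random.default_rng(seed)

    info: list[tuple[Segment, StrategyClass, frozenset[StrategyClass]]] = []
    for seg in segments:
        cov = gt.coverage(seg.trajectory.trajectory_id,
                          seg.start_arc, seg.end_arc)
        if not cov:
            continue
        ordered = sorted(cov.items(), key=lambda kv: (-kv[1], kv[0].value))
        labels = {ordered[0][0]}
        if len(ordered) > 1 and ordered[1][1] >= straddle_share * seg.arc_length:
            labels.add(ordered[1][0])
        info.append((seg, ordered[0][0], frozenset(labels)))

    n_target = int(round(fraction * len(segments)))
    by_class: dict[StrategyClass, list[int]] = {}
    for i, (_, major, _) in enumerate(info):
        by_class.setdefault(major, []).append(i)

    # largest-remainder allocation so the total is exact
    quotas = {c: fraction * len(ix) for c, ix in by_class.items()}
    alloc = {c: min(int(q), len(by_class[c])) for c, q in quotas.items()}
    remainder = sorted(by_class, key=lambda c: (quotas[c] - int(quotas[c]),
                                                c.value), reverse=True)
    i = 0
    while sum(alloc.values()) < min(n_target, len(info)):
        c = remainder[i % len(remainder)]
        if alloc[c] < len(by_class[c]):
            alloc[c] += 1
        i += 1

    records: list[LabelRecord] = []
    for c in sorted(by_class, key=lambda s: s.value):
        idx = np.array(by_class[c])
        take = rng.choice(len(idx), size=alloc[c], replace=False)
        for j in sorted(idx[take]):
            seg, _, labels = info[j]
            records.append(LabelRecord(segment_id=seg.segment_id,
                                       labels=labels))
    return records
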