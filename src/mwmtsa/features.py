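"""The eight per-segment path descriptors used for clustering.

All distances are normalised by the arena radius R so the vector is
invariant to a global rescaling of the setup, and every descriptor is a
function of relative geometry only, hence invariant under rotations and
translations of the whole arena.  Headings are computed after merging
sub-0.1 cm steps, which suppresses tracking jitter that would otherwise
dominate the turning-angle sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mwmtsa.arena_io import ArenaGeometry
from mwmtsa.segmentation import Segment

FEATURE_NAMES: tuple[str, ...] = (
    "median_dist_centre",     # R units
    "iqr_dist_centre",        # R units
    "focus",                  # [0, 1]; 1 = search confined to a tiny region
    "eccentricity",           # [0, 1]; 1 = perfectly linear point cloud
    "efficiency",             # [0, 1]; displacement / arc length
    "inner_radius_variation", # std/mean of distance to arena centre
    "sum_abs_turn",           # radians
    "min_dist_platform",      # R units
)

_MIN_STEP = 0.1  # cm; steps below this are merged before heading computation


@dataclass(frozen=True)
class FeatureVector:
    median_dist_centre: float
    iqr_dist_centre: float
    focus: float
    eccentricity: float
    efficiency: float
    inner_radius_variation: float
    sum_abs_turn: float
    min_dist_platform: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)


def _merge_small_steps(xy: np.ndarray, min_step: float = _MIN_STEP) -> np.ndarray:
    """Keep only points at least ``min_step`` from the last kept point."""
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    if np.all(steps >= min_step):
        return xy
    keep = [0]
    last = xy[0]
    for i in range(1, len(xy)):
        if np.hypot(xy[i, 0] - last[0], xy[i, 1] - last[1]) >= min_step:
            keep.append(i)
            last = xy[i]
    return xy[keep]


def compute_features(seg: Segment, arena: ArenaGeometry) -> FeatureVector:
    xy = seg.xy - arena.centre_xy
    if len(xy) < 3:
        raise ValueError("segment needs at least 3 points")
    if np.allclose(xy, xy[0]):
        raise ValueError("degenerate segment: all points identical")
    R = arena.radius
    L = max(seg.arc_length, 1e-12)

    r = np.linalg.norm(xy, axis=1)
    median_dist = float(np.median(r)) / R
    q75, q25 = np.percentile(r, [75, 25])
    iqr_dist = float(q75 - q25) / R

    centroid = xy.mean(axis=0)
    r_spread = float(np.mean(np.linalg.norm(xy - centroid, axis=1)))
    focus = float(np.clip(1.0 - 2.0 * r_spread / L, 0.0, 1.0))

    cov = np.cov(xy.T)
    lam = np.linalg.eigvalsh(cov)          # ascending
    lam = np.clip(lam, 0.0, None)
    ecc = float(np.sqrt(1.0 - lam[0] / lam[1])) if lam[1] > 0 else 0.0

    displacement = float(np.linalg.norm(xy[-1] - xy[0]))
    efficiency = float(np.clip(displacement / L, 0.0, 1.0))

    mean_r = float(np.mean(r))
    irv = float(np.std(r) / mean_r) if mean_r > 1e-12 else 0.0

    clean = _merge_small_steps(xy)
    if len(clean) >= 3:
        v = np.diff(clean, axis=0)
        h = np.arctan2(v[:, 1], v[:, 0])
        dh = np.diff(h)
        dh = np.arctan2(np.sin(dh), np.cos(dh))  # wrap to (-pi, pi]
        sum_turn = float(np.sum(np.abs(dh)))
    else:
        sum_turn = 0.0

    platform = arena.platform_xy - arena.centre_xy
    min_platform = float(np.min(np.linalg.norm(xy - platform, axis=1))) / R

    return FeatureVector(median_dist_centre=median_dist,
                         iqr_dist_centre=iqr_dist,
                         focus=focus,
                         eccentricity=ecc,
                         efficiency=efficiency,
                         inner_radius_variation=irv,
                         sum_abs_turn=sum_turn,
                         min_dist_platform=min_platform)


@dataclass
class FeatureScaling:
    """Per-column robust location/scale (median, IQR; zero IQR -> scale 1)."""

    location: np.ndarray
    scale: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.location) / self.scale


def feature_matrix(segments, arena: ArenaGeometry, standardise: bool = False,
                   scaling: FeatureScaling | None = None):
    """Stack per-segment features into a samples x 8 matrix.

    With ``standardise`` (or an explicit pre-fitted ``scaling``), columns are
    robustly centred and scaled; the scaling parameters are returned for
    reuse on new data.
    """
    if len(segments) == 0:
        raise ValueError("need at least one segment")
    X = np.vstack([compute_features(s, arena).as_array() for s in segments])
    if scaling is not None:
        return scaling.transform(X), scaling
    if not standardise:
        return X, None
    loc = np.median(X, axis=0)
    q75 = np.percentile(X, 75, axis=0)
    q25 = np.percentile(X, 25, axis=0)
    scale = q75 - q25
    zero = scale <= 1e-12
    if np.any(zero):
        import warnings
        warnings.warn("zero-IQR feature column(s); scale set to 1", stacklevel=2)
        scale = np.where(zero, 1.0, scale)
    scaling = FeatureScaling(location=loc, scale=scale)
    return scaling.transform(X), scaling
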