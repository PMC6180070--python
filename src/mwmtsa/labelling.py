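"""Partial expert labels and the pairwise constraints derived from them.

An expert labels a small fraction (ideally 8-12%) of segments with one or
two strategy codes.  Single-labelled segments sharing a class yield
must-link pairs; pairs with disjoint label sets yield cannot-link pairs.
Segments carrying two labels genuinely straddle classes, so they anchor no
must-links and generate no cannot-link against either of their own labels.
Pair sampling is capped per class (and per class pair) and seeded, since the
constrained-clustering cost grows with the constraint count, not the label
count.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from mwmtsa.strategies import StrategyClass, parse_strategy


@dataclass(frozen=True)
class LabelRecord:
    segment_id: str
    labels: frozenset[StrategyClass]

    def __post_init__(self) -> None:
        if not (1 <= len(self.labels) <= 2):
            raise ValueError("a record carries 1 or 2 labels")
        if StrategyClass.UNDEFINED in self.labels:
            raise ValueError("UNDEFINED is not a label")

    @property
    def single(self) -> bool:
        return len(self.labels) == 1

    @property
    def primary(self) -> StrategyClass:
        """Deterministic representative class (used for fold stratification)."""
        return min(self.labels, key=lambda c: c.value)


@dataclass
class ConstraintSet:
    must_link: set[frozenset[str]] = field(default_factory=set)
    cannot_link: set[frozenset[str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.must_link & self.cannot_link:
            raise ValueError("a pair cannot be both must-link and cannot-link")
        for pair in list(self.must_link) + list(self.cannot_link):
            if len(pair) != 2:
                raise ValueError("constraints are unordered pairs of distinct ids")

    def __len__(self) -> int:
        return len(self.must_link) + len(self.cannot_link)


@dataclass(frozen=True)
class CoverageReport:
    n_labelled: int
    n_segments: int
    fraction: float
    status: str  # LOW | OK | HIGH


def load_labels(path: str | Path) -> list[LabelRecord]:
    """Read a ``segment_id,label1[,label2]`` CSV into validated records."""
    path = Path(path)
    records: list[LabelRecord] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            row = [c.strip() for c in row if c.strip()]
            if not row or row[0].lower() == "segment_id":
                continue
            seg_id, *codes = row
            if seg_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate segment id {seg_id!r}")
            if not (1 <= len(codes) <= 2):
                raise ValueError(f"{path}:{lineno}: need 1 or 2 labels, got {len(codes)}")
            labels = frozenset(parse_strategy(c) for c in codes)
            seen.add(seg_id)
            records.append(LabelRecord(segment_id=seg_id, labels=labels))
    return records


def save_labels(records, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["segment_id", "label1", "label2"])
        for rec in records:
            codes = sorted(c.value for c in rec.labels)
            writer.writerow([rec.segment_id] + codes + [""] * (2 - len(codes)))


def _sample_pairs(pairs: list[frozenset[str]], cap: int,
                  rng: np.random.Generator) -> list[frozenset[str]]:
    if len(pairs) <= cap:
        return pairs
    idx = rng.choice(len(pairs), size=cap, replace=False)
    return [pairs[i] for i in sorted(idx)]


def derive_constraints(records, max_pairs_per_class: int = 500,
                       seed: int = 0) -> ConstraintSet:
    """Turn label records into seeded, capped must-/cannot-link pairs."""
    records = list(records)
    if len(records) < 2:
        return ConstraintSet()
    rng = np.random.default_rng(seed)

    by_class: dict[StrategyClass, list[str]] = {}
    for rec in records:
        if rec.single:
            by_class.setdefault(next(iter(rec.labels)), []).append(rec.segment_id)

    must: set[frozenset[str]] = set()
    for cls in sorted(by_class, key=lambda c: c.value):
        ids = sorted(by_class[cls])
        pairs = [frozenset(p) for p in combinations(ids, 2)]
        must.update(_sample_pairs(pairs, max_pairs_per_class, rng))

    # cannot-link: disjoint label sets only, capped per unordered class-set pair
    by_labelset: dict[frozenset[StrategyClass], list[str]] = {}
    for rec in records:
        by_labelset.setdefault(rec.labels, []).append(rec.segment_id)
    cannot: set[frozenset[str]] = set()
    keys = sorted(by_labelset, key=lambda s: sorted(c.value for c in s))
    for i, ka in enumerate(keys):
        for kb in keys[i + 1:]:
            if ka & kb:
                continue
            pairs = [frozenset((a, b))
                     for a in sorted(by_labelset[ka])
                     for b in sorted(by_labelset[kb])]
            cannot.update(_sample_pairs(pairs, max_pairs_per_class, rng))
    return ConstraintSet(must_link=must, cannot_link=cannot)


def coverage_report(n_labelled: int, n_segments: int) -> CoverageReport:
    """Compare labelling coverage against the recommended 8-12% band."""
    if n_segments <= 0:
        raise ValueError("n_segments must be positive")
    frac = n_labelled / n_segments
    status = "OK" if 0.08 <= frac <= 0.12 else ("LOW" if frac < 0.08 else "HIGH")
    return CoverageReport(n_labelled=n_labelled, n_segments=n_segments,
                          fraction=frac, status=status)
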