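"""End-to-end orchestration: tracks -> segments -> features -> ensemble ->
smoothing -> group statistics, with CSV/JSON artefacts and optional figures.

A run either completes with the full artefact set or fails with the stage
name attached; too few CV-strong classifiers aborts early with the
"insufficient labelling" diagnostic, the cue to provide more or better
labels.  All randomness descends from the single master seed recorded in
the summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mwmtsa import ensemble as ens
from mwmtsa import smoothing, stats
from mwmtsa.arena_io import (ArenaGeometry, ReaderOptions, Trajectory,
                             path_metrics, read_tracks)
from mwmtsa.features import FEATURE_NAMES, feature_matrix
from mwmtsa.labelling import (ConstraintSet, coverage_report,
                              derive_constraints, load_labels)
from mwmtsa.segmentation import SegmentationConfig, segment_cohort
from mwmtsa.smoothing import SmoothingConfig
from mwmtsa.strategies import LABELLABLE, StrategyClass

log = logging.getLogger(__name__)

#: Measures compared between groups: the eight searched strategies plus the
#: transition count.  Direct finding is reported but not compared (its whole-
#: path statistics carry no segmentation-specific information).
COMPARED_MEASURES: tuple[str, ...] = (
    "TT", "IC", "SC", "FS", "CR", "SO", "SS", "ST", "transitions")

PATH_MEASURES: tuple[str, ...] = ("escape_latency", "path_length", "mean_speed")


@dataclass
class RunConfig:
    arena: ArenaGeometry = field(default_factory=ArenaGeometry)
    segmentation: SegmentationConfig = field(
        default_factory=lambda: SegmentationConfig(segment_length=250.0,
                                                   overlap=0.90))
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    K_range: tuple[int, int] = (10, 100)       # inclusive bounds
    error_threshold: float = 0.25
    min_members: int = 40
    max_constraint_pairs: int = 500
    mpck_max_iter: int = 30    # assignments essentially converge by ~30 sweeps
    seed: int = 0
    tracks_path: str | None = None
    labels_path: str | None = None
    reader: ReaderOptions = field(default_factory=ReaderOptions)
    output_dir: str | None = None
    figure_format: str = "png"
    make_figures: bool = False
    member_cis: bool = True    # per-member significance votes (binomial CIs)

    def __post_init__(self) -> None:
        lo, hi = self.K_range
        if not (2 <= lo <= hi):
            raise ValueError("invalid K range")
        if not (0 < self.error_threshold <= 1):
            raise ValueError("error threshold must be a fraction in (0, 1]")


@dataclass
class RunResult:
    config: RunConfig
    n_segments: int
    coverage: object
    pool: list
    ensemble: ens.Ensemble
    segment_classes: np.ndarray
    classifications: dict[Trajectory, list]
    profile: pd.DataFrame
    transitions: pd.DataFrame
    measures: pd.DataFrame
    stats_table: pd.DataFrame
    summary: dict


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except ens.InsufficientLabellingError:
                raise
            except Exception as e:  # noqa: BLE001 - re-raise with stage name
                raise StageError(name, e) from e
        return wrapped
    return deco


def run_analysis(config: RunConfig, trajectories: list[Trajectory] | None = None,
                 records=None) -> RunResult:
    """Execute the full workflow; see the module docstring for the stages."""
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    if trajectories is None:
        if not config.tracks_path:
            raise ValueError("either trajectories or tracks_path required")
        trajectories = _stage("read")(read_tracks)(
            config.tracks_path, config.arena, config.reader)
    if records is None:
        if not config.labels_path:
            raise ValueError("either records or labels_path required")
        records = _stage("labels")(load_labels)(config.labels_path)

    segments, short = _stage("segment")(segment_cohort)(
        trajectories, config.segmentation)
    if not segments:
        raise StageError("segment", ValueError("no segmentable trajectories"))
    segment_ids = [s.segment_id for s in segments]
    known = set(segment_ids)
    records = [r for r in records if r.segment_id in known]

    X, scaling = _stage("features")(feature_matrix)(
        segments, config.arena, standardise=True)
    cov = coverage_report(len(records), len(segments))
    if cov.status != "OK":
        log.warning("labelling coverage %.1f%% is %s (recommended 8-12%%)",
                    100 * cov.fraction, cov.status)
    constraints = _stage("constraints")(derive_constraints)(
        records, config.max_constraint_pairs, seed=config.seed)

    lo, hi = config.K_range
    pool = _stage("pool")(ens.build_pool)(
        X, records, constraints, K_range=range(lo, hi + 1),
        seed=config.seed, segment_ids=segment_ids,
        max_iter=config.mpck_max_iter)
    ensemble = ens.select_strong(pool, config.error_threshold,
                                 config.min_members)

    codes = ens.vote_matrix(ensemble, X)
    final_classes = _stage("vote")(_vote_from_codes)(codes)
    unclassified, unc_status = ens.unclassified_rate(final_classes)

    classifications, weights = _stage("smoothing")(_smooth_cohort)(
        trajectories, segments, final_classes, config)
    profile, transitions = smoothing.strategy_profile(classifications)
    measures = smoothing.per_animal_measures(classifications)
    measures = measures.merge(_path_measures(trajectories),
                              on=["group", "animal_id", "trial"])

    two_groups = measures["group"].nunique() == 2
    stats_rows = []
    member_sig: dict[str, list[int]] = {m: [] for m in COMPARED_MEASURES}
    if two_groups:
        for m in COMPARED_MEASURES + PATH_MEASURES:
            fr = stats.group_compare(measures, m)
            stats_rows.append({"measure": m, "Q": fr.Q, "df": fr.df,
                               "p": fr.p, "significant": fr.significant})
        if config.member_cis:
            member_sig = _stage("member_stats")(_per_member_significance)(
                trajectories, segments, codes, ensemble, config)
    stats_table = pd.DataFrame(stats_rows)

    cis = {}
    for m, outcomes in member_sig.items():
        if outcomes:
            cis[m] = stats.vote_significance_ci(outcomes)

    agreement = ens.agreement_matrix(codes)
    sub = ens.subsample_ensembles(ensemble, n_ensembles=21, members_each=11,
                                  seed=config.seed)
    sub_preds = np.vstack([ens.majority_vote_codes(ens.vote_matrix(e, X))
                           for e in sub]) if len(ensemble.members) >= 11 else None
    sub_agreement = (ens.agreement_matrix(sub_preds).mean_off_diagonal
                     if sub_preds is not None else float("nan"))

    summary = {
        "seed": config.seed,
        "n_trajectories": len(trajectories),
        "n_short_trajectories": len(short),
        "n_segments": len(segments),
        "coverage_fraction": cov.fraction,
        "coverage_status": cov.status,
        "pool_size": len(pool),
        "n_strong": len(ensemble.members),
        "mean_member_cv_error": float(np.mean(
            [m.cv_error for m in ensemble.members])),
        "ensemble_cv_error": ens.ensemble_cv_error(ensemble, records),
        "unclassified_rate": unclassified,
        "unclassified_status": unc_status,
        "classifier_agreement_pct": agreement.mean_off_diagonal,
        "ensemble_agreement_pct": sub_agreement,
        "stats": {r["measure"]: {"Q": r["Q"], "p": r["p"],
                                 "significant": bool(r["significant"])}
                  for r in stats_rows},
        "binomial_ci": {m: dataclasses.asdict(ci) for m, ci in cis.items()},
    }

    result = RunResult(config=config, n_segments=len(segments), coverage=cov,
                       pool=pool, ensemble=ensemble,
                       segment_classes=final_classes,
                       classifications=classifications, profile=profile,
                       transitions=transitions, measures=measures,
                       stats_table=stats_table, summary=summary)
    if out_dir:
        _stage("artefacts")(_write_artefacts)(result, segments, X, out_dir)
        if config.make_figures:
            _stage("figures")(_write_figures)(result, out_dir)
    return result


def _vote_from_codes(codes: np.ndarray) -> np.ndarray:
    from mwmtsa.strategies import INDEX_CLASS
    return np.array([INDEX_CLASS[c] for c in ens.majority_vote_codes(codes)],
                    dtype=object)


def _smooth_cohort(trajectories, segments, classes, config: RunConfig):
    weights = smoothing.class_weights(
        smoothing.segment_class_distribution(classes),
        config.smoothing.weight_bounds)
    by_traj: dict[Trajectory, list] = {}
    seg_by_traj: dict[Trajectory, tuple[list, list]] = {}
    for seg, cls in zip(segments, classes):
        segs, cl = seg_by_traj.setdefault(seg.trajectory, ([], []))
        segs.append(seg)
        cl.append(cls)
    for traj in trajectories:
        segs, cl = seg_by_traj.get(traj, ([], []))
        ics = smoothing.classify_trajectory_intervals(
            traj, segs, cl, config.smoothing, weights, R=config.arena.radius)
        by_traj[traj] = ics
    return by_traj, weights


def _path_measures(trajectories) -> pd.DataFrame:
    rows = []
    for traj in trajectories:
        pm = path_metrics(traj)
        rows.append({"group": traj.group, "animal_id": traj.animal_id,
                     "trial": traj.trial,
                     "escape_latency": pm.escape_latency,
                     "path_length": pm.path_length,
                     "mean_speed": pm.mean_speed})
    return pd.DataFrame(rows)


def _per_member_significance(trajectories, segments, codes, ensemble,
                             config: RunConfig) -> dict[str, list[int]]:
    """Each member classifies alone, is smoothed alone, and votes 1/0 on the
    significance of every compared measure."""
    from mwmtsa.strategies import INDEX_CLASS
    out: dict[str, list[int]] = {m: [] for m in COMPARED_MEASURES}
    for row in codes:
        member_classes = np.array([INDEX_CLASS[c] for c in row], dtype=object)
        try:
            classifications, _ = _smooth_cohort(trajectories, segments,
                                                member_classes, config)
        except ValueError:   # a member that classified nothing
            continue
        measures = smoothing.per_animal_measures(classifications)
        for m in COMPARED_MEASURES:
            fr = stats.group_compare(measures, m)
            out[m].append(int(fr.significant))
    return out


def _write_artefacts(result: RunResult, segments, X, out_dir: Path) -> None:
    seg_rows = [{
        "segment_id": s.segment_id,
        "trajectory_id": s.trajectory.trajectory_id, "ordinal": s.ordinal,
        "start_index": s.start_index, "end_index": s.end_index,
        "start_arc": s.start_arc, "end_arc": s.end_arc,
        "class": result.segment_classes[i].value,
    } for i, s in enumerate(segments)]
    pd.DataFrame(seg_rows).to_csv(out_dir / "segments.csv", index=False)
    feat = pd.DataFrame(X, columns=list(FEATURE_NAMES))
    feat.insert(0, "segment_id", [s.segment_id for s in segments])
    feat.to_csv(out_dir / "features.csv", index=False)
    pd.DataFrame([{"K": m.K, "seed": m.seed, "cv_error": m.cv_error,
                   "selected": m.cv_error < result.config.error_threshold}
                  for m in result.pool]).to_csv(out_dir / "pool.csv",
                                                index=False)
    iv_rows = []
    for traj, ics in result.classifications.items():
        for ic in ics:
            iv_rows.append({"trajectory_id": traj.trajectory_id,
                            "ordinal": ic.interval.ordinal,
                            "class": ic.strategy.value,
                            **{f"vote_{c.value}": v
                               for c, v in ic.vote_sums.items()}})
    pd.DataFrame(iv_rows).to_csv(out_dir / "intervals.csv", index=False)
    result.profile.to_csv(out_dir / "profile.csv", index=False)
    result.transitions.to_csv(out_dir / "transitions.csv", index=False)
    result.measures.to_csv(out_dir / "measures.csv", index=False)
    result.stats_table.to_csv(out_dir / "stats.csv", index=False)
    (out_dir / "summary.json").write_text(
        json.dumps(result.summary, indent=1, default=float))


def _write_figures(result: RunResult, out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fmt = result.config.figure_format
    groups = sorted(result.measures["group"].unique())

    fig, axes = plt.subplots(3, 3, figsize=(12, 9), sharex=True)
    for ax, m in zip(axes.ravel(), COMPARED_MEASURES):
        for g in groups:
            sub = result.measures[result.measures["group"] == g]
            per_trial = sub.groupby("trial")[m].mean()
            ax.plot(per_trial.index, 100 * per_trial.values if m != "transitions"
                    else per_trial.values, marker="o", label=g)
        ax.set_title(m)
    axes[0, 0].legend(fontsize=8)
    fig.suptitle("strategy share per trial (%) and transitions")
    fig.savefig(out_dir / f"strategies.{fmt}", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    for ax, m in zip(axes, PATH_MEASURES):
        data = [result.measures[result.measures["group"] == g]
                .groupby("trial")[m].mean().values for g in groups]
        ax.boxplot(data, tick_labels=groups)
        ax.set_title(m)
    fig.savefig(out_dir / f"path_metrics.{fmt}", dpi=120)
    plt.close(fig)

    cis = result.summary.get("binomial_ci", {})
    if cis:
        fig, ax = plt.subplots(figsize=(7, 3.5))
        names = list(cis)
        means = [cis[m]["mean"] for m in names]
        lows = [cis[m]["low"] for m in names]
        highs = [cis[m]["high"] for m in names]
        xs = np.arange(len(names))
        ax.errorbar(xs, means,
                    yerr=[np.array(means) - lows, np.array(highs) - means],
                    fmt="s", capsize=3)
        ax.axhline(0.5, ls="--", color="grey")
        ax.set_xticks(xs, names)
        ax.set_ylim(-0.02, 1.02)
        ax.set_ylabel("fraction of members significant")
        fig.savefig(out_dir / f"member_confidence.{fmt}", dpi=120)
        plt.close(fig)


def compare_segmentations(results: list[RunResult]) -> pd.DataFrame:
    """Cross-configuration consistency of the group-difference conclusions.

    One row per compared measure (eight strategies plus transitions); one
    significance column per run, CI bounds where available, and a
    ``consistent`` flag marking measures on which every run agrees.
    """
    if len(results) < 2:
        raise ValueError("need at least two runs to compare")
    n0 = results[0].summary["n_trajectories"]
    if any(r.summary["n_trajectories"] != n0 for r in results):
        raise ValueError("runs cover different cohorts")
    rows = []
    for m in COMPARED_MEASURES:
        row: dict = {"measure": m}
        flags = []
        for i, r in enumerate(results):
            tag = f"run{i + 1}"
            st = r.summary["stats"].get(m)
            sig = bool(st["significant"]) if st else False
            row[f"{tag}_p"] = st["p"] if st else np.nan
            row[f"{tag}_significant"] = sig
            ci = r.summary["binomial_ci"].get(m)
            row[f"{tag}_ci_low"] = ci["low"] if ci else np.nan
            row[f"{tag}_ci_high"] = ci["high"] if ci else np.nan
            flags.append(sig)
        row["consistent"] = len(set(flags)) == 1
        rows.append(row)
    return pd.DataFrame(rows)
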