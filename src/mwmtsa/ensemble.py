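"""Classifier pool generation, CV gating and equal-weight majority voting.

One MPCK classifier is fitted per target cluster count K (10..100 by
default); only members with 10-fold cross-validation error strictly below
25% join the ensemble, and at least 40 such members are required before any
classification is trusted — too few strong classifiers means the labelling
stage needs more or better labels.  Votes carry equal weight; member
abstentions (UNDEFINED) are discarded before counting, and a strict tie for
the top count leaves the segment undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mwmtsa import mpck
from mwmtsa.labelling import ConstraintSet
from mwmtsa.mpck import CvResult, MpckModel
from mwmtsa.strategies import (CLASS_INDEX, INDEX_CLASS, UNDEFINED_INDEX,
                               StrategyClass)


class InsufficientLabellingError(RuntimeError):
    """Raised when too few classifiers pass the CV gate.

    The remedy is more (or more consistent) expert labels, not a different
    threshold.
    """


@dataclass
class ClassifierRecord:
    model: MpckModel
    K: int
    seed: int
    cv_error: float
    cv: CvResult

    def __post_init__(self) -> None:
        if not (0.0 <= self.cv_error <= 1.0):
            raise ValueError("cv_error must be a fraction")


@dataclass
class Ensemble:
    members: list[ClassifierRecord]
    error_threshold: float = 0.25
    min_members: int = 40

    def __post_init__(self) -> None:
        bad = [m.K for m in self.members if m.cv_error >= self.error_threshold]
        if bad:
            raise ValueError(f"members above the error threshold: K={bad}")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class AgreementMatrix:
    percentages: np.ndarray   # symmetric, diagonal exactly 100
    mean_off_diagonal: float


def build_pool(features: np.ndarray, records, constraints: ConstraintSet,
               K_range=range(10, 101), seed: int = 0, *, segment_ids,
               **fit_kw) -> list[ClassifierRecord]:
    """Fit and cross-validate one classifier per target cluster count.

    Member seeds derive deterministically from the master seed and K; the CV
    fold split is shared across the pool (seeded by the master seed alone) so
    member hold-out predictions can later be combined fold-consistently.
    """
    pool: list[ClassifierRecord] = []
    for K in K_range:
        k_seed = (seed * 100003 + K) % (2 ** 31)
        cv = mpck.cross_validate(features, records, constraints, K,
                                 seed=k_seed, segment_ids=segment_ids,
                                 fold_seed=seed, **fit_kw)
        model = mpck.fit(features, constraints, K, seed=k_seed,
                         segment_ids=segment_ids, **fit_kw)
        mpck.map_clusters_to_classes(model, features, records, segment_ids)
        pool.append(ClassifierRecord(model=model, K=K, seed=k_seed,
                                     cv_error=cv.error, cv=cv))
    return pool


def select_strong(pool, threshold: float = 0.25,
                  min_members: int = 40) -> Ensemble:
    """Keep members with CV error strictly below ``threshold``."""
    if not pool:
        raise ValueError("empty classifier pool")
    strong = [m for m in pool if m.cv_error < threshold]
    if len(strong) < min_members:
        raise InsufficientLabellingError(
            f"only {len(strong)} of {len(pool)} classifiers have CV error "
            f"below {threshold:.0%} (minimum {min_members}); provide more or "
            f"more consistent labels and re-run")
    return Ensemble(members=strong, error_threshold=threshold,
                    min_members=min_members)


def _to_codes(preds: np.ndarray) -> np.ndarray:
    return np.array([CLASS_INDEX.get(p, UNDEFINED_INDEX) for p in preds],
                    dtype=int)


def vote_matrix(ensemble: Ensemble, features: np.ndarray) -> np.ndarray:
    """members x segments matrix of integer class codes."""
    return np.vstack([_to_codes(mpck.predict(m.model, features))
                      for m in ensemble.members])


def majority_vote_codes(codes: np.ndarray) -> np.ndarray:
    """Modal class code per column; abstentions discarded, ties undefined."""
    n_members, n_seg = codes.shape
    counts = np.zeros((UNDEFINED_INDEX, n_seg), dtype=int)
    for c in range(UNDEFINED_INDEX):
        counts[c] = np.sum(codes == c, axis=0)
    top = counts.max(axis=0)
    n_top = np.sum(counts == top[None, :], axis=0)
    winner = counts.argmax(axis=0)
    out = np.where((top > 0) & (n_top == 1), winner, UNDEFINED_INDEX)
    return out


def majority_vote(ensemble: Ensemble, features: np.ndarray) -> np.ndarray:
    """Per-segment strategy class under equal-weight majority voting."""
    codes = vote_matrix(ensemble, features)
    return np.array([INDEX_CLASS[c] for c in majority_vote_codes(codes)],
                    dtype=object)


def agreement_matrix(predictions: np.ndarray) -> AgreementMatrix:
    """Pairwise percentage of segments on which two classifiers agree."""
    P = np.asarray(predictions)
    if P.ndim != 2 or len(P) < 1:
        raise ValueError("predictions must be an n_classifiers x n_segments matrix")
    n = len(P)
    M = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = 100.0 * float(np.mean(P[i] == P[j]))
    if n > 1:
        iu = np.triu_indices(n, k=1)
        mean_off = float(np.mean(M[iu]))
    else:
        mean_off = float("nan")
    return AgreementMatrix(percentages=M, mean_off_diagonal=mean_off)


def unclassified_rate(final_classes) -> tuple[float, str]:
    """Fraction of UNDEFINED outcomes; WARN at or above the 3% guideline."""
    arr = list(final_classes)
    if not arr:
        raise ValueError("no classifications given")
    frac = sum(1 for c in arr if c is StrategyClass.UNDEFINED) / len(arr)
    return frac, ("WARN" if frac >= 0.03 else "OK")


def ensemble_cv_error(ensemble: Ensemble, records) -> float:
    """Hold-out error of the majority vote over the members' shared CV folds.

    Every member stored the prediction it made for each labelled segment when
    that segment's fold was held out; voting those predictions scores the
    ensemble on exactly the folds its members were scored on.
    """
    records = list(records)
    n_err = 0
    n_tot = 0
    for rec in records:
        votes = [m.cv.held_out.get(rec.segment_id) for m in ensemble.members]
        votes = [v for v in votes if v is not None]
        if not votes:
            continue
        codes = np.array([[CLASS_INDEX.get(v, UNDEFINED_INDEX)] for v in votes])
        final = INDEX_CLASS[int(majority_vote_codes(codes)[0])]
        n_tot += 1
        if final not in rec.labels:
            n_err += 1
    return n_err / n_tot if n_tot else 0.0


def subsample_ensembles(ensemble: Ensemble, n_ensembles: int = 21,
                        members_each: int = 11, seed: int = 0) -> list[Ensemble]:
    """Random member subsets used for the between-ensemble agreement check."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_ensembles):
        take = min(members_each, len(ensemble.members))
        idx = rng.choice(len(ensemble.members), size=take, replace=False)
        out.append(Ensemble(members=[ensemble.members[i] for i in sorted(idx)],
                            error_threshold=ensemble.error_threshold,
                            min_members=0))
    return out
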