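"""Metric Pairwise Constrained K-Means (MPCK-Means) as a strategy classifier.

The clusterer combines the two semi-supervised ingredients: pairwise
must-/cannot-link constraints (constraint-based learning) and a per-cluster
diagonal Mahalanobis metric re-estimated each iteration (metric learning).
The per-point assignment cost is

    sum_d a_kd (x_d - mu_kd)^2  -  sum_d log a_kd  +  penalty terms,

i.e. the negative log-density of an axis-aligned Gaussian up to constants,
plus a constant penalty for each violated constraint.  Coordinate descent
(assign, re-centre, re-estimate metrics) makes the objective non-increasing:
each phase exactly minimises its block, the metric block having the closed
form a_kd = n_k / S_kd clipped into the allowed range.  Keeping violation
penalties out of the metric update preserves that exactness.

Clusters become a classifier by mapping each cluster to the modal expert
class among its labelled members; clusters with no labelled member, or a
tied vote, stay unassigned and predict UNDEFINED.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mwmtsa.labelling import ConstraintSet, LabelRecord
from mwmtsa.strategies import StrategyClass

_A_LO, _A_HI = 1e-6, 1e3   # metric weight bounds (standardised units)


@dataclass
class MpckModel:
    K: int
    centroids: np.ndarray                      # K x d
    metric_weights: np.ndarray                 # K x d, strictly positive
    cluster_to_class: dict[int, StrategyClass | None]
    seed: int
    objective: float
    objective_history: list[float] = field(default_factory=list)
    labels_: np.ndarray | None = None          # training-time assignment
    n_iter: int = 0

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "seed": self.seed,
            "objective": self.objective,
            "centroids": self.centroids.tolist(),
            "metric_weights": self.metric_weights.tolist(),
            "cluster_to_class": {
                str(k): (v.value if v is not None else None)
                for k, v in self.cluster_to_class.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MpckModel":
        return cls(K=d["K"], seed=d["seed"], objective=d["objective"],
                   centroids=np.asarray(d["centroids"], float),
                   metric_weights=np.asarray(d["metric_weights"], float),
                   cluster_to_class={
                       int(k): (StrategyClass(v) if v is not None else None)
                       for k, v in d["cluster_to_class"].items()
                   })


@dataclass(frozen=True)
class CvResult:
    folds: int
    error: float
    per_fold_errors: tuple[float, ...]
    held_out: dict[str, StrategyClass]   # per labelled segment id


def constraints_to_indices(constraints: ConstraintSet,
                           segment_ids) -> tuple[np.ndarray, np.ndarray]:
    """Resolve id pairs to row-index pairs; pairs outside ``segment_ids`` drop."""
    pos = {sid: i for i, sid in enumerate(segment_ids)}

    def resolve(pairs):
        out = []
        for pair in sorted(pairs, key=lambda p: tuple(sorted(p))):
            a, b = sorted(pair)
            if a in pos and b in pos:
                out.append((pos[a], pos[b]))
        return np.array(out, dtype=int).reshape(-1, 2)

    return resolve(constraints.must_link), resolve(constraints.cannot_link)


def _union_find_neighbourhoods(n: int, ml: np.ndarray) -> list[np.ndarray]:
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in ml:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    roots = np.array([find(i) for i in range(n)])
    groups: dict[int, list[int]] = {}
    for i, r in enumerate(roots):
        groups.setdefault(r, []).append(i)
    hoods = [np.array(g) for g in groups.values() if len(g) > 1]
    hoods.sort(key=len, reverse=True)
    return hoods


def _init_centroids(X: np.ndarray, K: int, ml: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Must-link neighbourhood means first, remainder by farthest-first."""
    n = len(X)
    hoods = _union_find_neighbourhoods(n, ml)
    centroids = [X[h].mean(axis=0) for h in hoods[:K]]
    if not centroids:
        centroids = [X[rng.integers(n)]]
    C = np.array(centroids)
    d2min = np.min(((X[:, None, :] - C[None]) ** 2).sum(-1), axis=1)
    while len(C) < K:
        nxt = X[int(np.argmax(d2min))]
        C = np.vstack([C, nxt])
        d2min = np.minimum(d2min, ((X - nxt) ** 2).sum(-1))
    return C[:K].copy()


def _base_cost(X2: np.ndarray, X: np.ndarray, Mu: np.ndarray,
               A: np.ndarray) -> np.ndarray:
    """n x K matrix of weighted squared distance minus log-det reward."""
    t1 = X2 @ A.T
    t2 = -2.0 * (X @ (A * Mu).T)
    t3 = np.sum(A * Mu * Mu, axis=1)
    t4 = -np.sum(np.log(A), axis=1)
    return t1 + t2 + (t3 + t4)[None, :]


def _penalty(labels: np.ndarray, ml: np.ndarray, cl: np.ndarray,
             w_ml: float, w_cl: float) -> float:
    p = 0.0
    if len(ml):
        p += w_ml * float(np.sum(labels[ml[:, 0]] != labels[ml[:, 1]]))
    if len(cl):
        p += w_cl * float(np.sum(labels[cl[:, 0]] == labels[cl[:, 1]]))
    return p


def fit(features: np.ndarray, constraints: ConstraintSet | None, K: int,
        seed: int, segment_ids=None, *, learn_metrics: bool = True,
        ml_penalty: float = 1.0, cl_penalty: float = 1.0,
        max_iter: int = 200, tol: float = 0.0) -> MpckModel:
    """Run MPCK-Means to an assignment fixpoint (or ``max_iter``).

    ``constraints`` may be ``None`` (plain clustering), a :class:`ConstraintSet`
    of segment-id pairs (requires ``segment_ids`` aligned with the feature
    rows), or a pre-resolved ``(must_idx, cannot_idx)`` pair of index arrays.
    With ``learn_metrics=False`` the metrics stay frozen at identity and the
    procedure reduces to constrained (or, without constraints, plain) k-means.
    ``tol`` relaxes the fixpoint: iteration stops once the fraction of
    points changing cluster drops to ``tol`` or below (0 = exact fixpoint).
    """
    X = np.ascontiguousarray(features, dtype=float)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("features must be a non-empty 2-D matrix")
    n, d = X.shape
    if K < 2:
        raise ValueError("K must be at least 2")
    if K > n:
        raise ValueError(f"K={K} exceeds the {n} available samples")

    if constraints is None:
        ml = cl = np.empty((0, 2), dtype=int)
    elif isinstance(constraints, ConstraintSet):
        if segment_ids is None:
            raise ValueError("segment_ids required to resolve a ConstraintSet")
        ml, cl = constraints_to_indices(constraints, segment_ids)
    else:
        ml, cl = (np.asarray(c, dtype=int).reshape(-1, 2) for c in constraints)

    rng = np.random.default_rng(seed)
    Mu = _init_centroids(X, K, ml, rng)
    A = np.ones((K, d))
    X2 = X * X

    constrained = np.unique(np.concatenate([ml.ravel(), cl.ravel()])) \
        if (len(ml) or len(cl)) else np.empty(0, dtype=int)
    ml_by_pt: dict[int, np.ndarray] = {}
    cl_by_pt: dict[int, np.ndarray] = {}
    for a, b in ml:
        ml_by_pt.setdefault(a, []).append(b)  # type: ignore[union-attr]
        ml_by_pt.setdefault(b, []).append(a)  # type: ignore[union-attr]
    for a, b in cl:
        cl_by_pt.setdefault(a, []).append(b)  # type: ignore[union-attr]
        cl_by_pt.setdefault(b, []).append(a)  # type: ignore[union-attr]
    ml_by_pt = {i: np.asarray(p, dtype=int) for i, p in ml_by_pt.items()}
    cl_by_pt = {i: np.asarray(p, dtype=int) for i, p in cl_by_pt.items()}

    labels = None
    history: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        base = _base_cost(X2, X, Mu, A)
        new = np.argmin(base, axis=1)
        if labels is not None and len(constrained):
            # constrained points keep their previous assignment as the greedy
            # starting point; single-point updates can then only lower the cost
            new[constrained] = labels[constrained]
        work = new
        if len(constrained):
            order = rng.permutation(constrained)
            for i in order:
                cost_i = base[i].copy()
                ml_p = ml_by_pt.get(i)
                if ml_p is not None:
                    # violated must-links: partners in a *different* cluster
                    agree = np.bincount(work[ml_p], minlength=K)
                    cost_i += ml_penalty * (len(ml_p) - agree)
                cl_p = cl_by_pt.get(i)
                if cl_p is not None:
                    cost_i += cl_penalty * np.bincount(work[cl_p], minlength=K)
                work[i] = int(np.argmin(cost_i))

        if labels is None:
            converged = False
        else:
            n_changed = int(np.sum(work != labels))
            converged = n_changed <= tol * n
        labels = work

        # centroid update via per-dimension bincounts; empty clusters keep
        # their previous centroid
        counts = np.bincount(labels, minlength=K).astype(float)
        occupied = counts > 0
        sums = np.empty((K, d))
        for j in range(d):
            sums[:, j] = np.bincount(labels, weights=X[:, j], minlength=K)
        Mu[occupied] = sums[occupied] / counts[occupied, None]

        if learn_metrics:
            dev2 = (X - Mu[labels]) ** 2
            S = np.empty((K, d))
            for j in range(d):
                S[:, j] = np.bincount(labels, weights=dev2[:, j], minlength=K)
            A[occupied] = np.clip(
                counts[occupied, None] / np.maximum(S[occupied], 1e-12),
                _A_LO, _A_HI)

        base = _base_cost(X2, X, Mu, A)
        obj = float(base[np.arange(n), labels].sum()
                    + _penalty(labels, ml, cl, ml_penalty, cl_penalty))
        history.append(obj)
        if converged:
            break

    return MpckModel(K=K, centroids=Mu, metric_weights=A,
                     cluster_to_class={k: None for k in range(K)},
                     seed=seed, objective=history[-1],
                     objective_history=history, labels_=labels,
                     n_iter=n_iter)


def map_clusters_to_classes(model: MpckModel, features: np.ndarray,
                            records, segment_ids) -> MpckModel:
    """Map each cluster to the modal expert class among its labelled members.

    A record with two labels contributes weight 1/2 to each; clusters with no
    labelled member or a tied modal vote stay unassigned.
    """
    if model.labels_ is None:
        raise ValueError("model must be fitted before mapping")
    pos = {sid: i for i, sid in enumerate(segment_ids)}
    votes: dict[int, dict[StrategyClass, float]] = {k: {} for k in range(model.K)}
    for rec in records:
        i = pos.get(rec.segment_id)
        if i is None:
            continue
        k = int(model.labels_[i])
        w = 1.0 / len(rec.labels)
        for cls in rec.labels:
            votes[k][cls] = votes[k].get(cls, 0.0) + w
    mapping: dict[int, StrategyClass | None] = {}
    for k in range(model.K):
        if not votes[k]:
            mapping[k] = None
            continue
        best = max(votes[k].values())
        winners = [c for c, v in votes[k].items() if v >= best - 1e-12]
        mapping[k] = winners[0] if len(winners) == 1 else None
    model.cluster_to_class = mapping
    return model


def assign_clusters(model: MpckModel, features: np.ndarray) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    if X.shape[1] != model.centroids.shape[1]:
        raise ValueError("feature dimension mismatch")
    base = _base_cost(X * X, X, model.centroids, model.metric_weights)
    return np.argmin(base, axis=1)


def predict(model: MpckModel, features: np.ndarray) -> np.ndarray:
    """Per-sample strategy classes (UNDEFINED where the cluster is unmapped)."""
    clusters = assign_clusters(model, features)
    out = np.empty(len(clusters), dtype=object)
    for i, k in enumerate(clusters):
        cls = model.cluster_to_class.get(int(k))
        out[i] = cls if cls is not None else StrategyClass.UNDEFINED
    return out


def stratified_folds(records, n_folds: int, seed: int) -> list[np.ndarray]:
    """Seeded stratified folds over label records.

    Stratification uses each record's representative class so rare classes
    spread across folds; classes with fewer members than folds simply appear
    in fewer folds (a hard failure would make rare strategies untestable).
    """
    rng = np.random.default_rng(seed)
    by_class: dict[StrategyClass, list[int]] = {}
    for i, rec in enumerate(records):
        by_class.setdefault(rec.primary, []).append(i)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    offset = 0
    for cls in sorted(by_class, key=lambda c: c.value):
        idx = np.array(by_class[cls])
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[(j + offset) % n_folds].append(int(i))
        offset += len(idx)
    return [np.array(sorted(f), dtype=int) for f in folds]


def _filter_constraints(ml: np.ndarray, cl: np.ndarray,
                        allowed_rows: set[int]):
    def keep(pairs):
        if not len(pairs):
            return pairs
        mask = np.array([a in allowed_rows and b in allowed_rows
                         for a, b in pairs])
        return pairs[mask]
    return keep(ml), keep(cl)


def cross_validate(features: np.ndarray, records, constraints: ConstraintSet,
                   K: int, seed: int, segment_ids, *, n_folds: int = 10,
                   fold_seed: int | None = None, **fit_kw) -> CvResult:
    """10-fold cross-validation error of the cluster-classifier.

    Folds are stratified over the labelled records.  Each fold refits on the
    full feature matrix (clustering stays transductive) but with constraints
    restricted to pairs of train-fold labelled segments, maps clusters using
    train-fold records only, and scores the held-out records: a prediction is
    correct when it falls inside the record's label set; UNDEFINED counts as
    an error.
    """
    records = list(records)
    if len(records) < n_folds:
        raise ValueError(f"need at least {n_folds} labelled records")
    pos = {sid: i for i, sid in enumerate(segment_ids)}
    ml, cl = constraints_to_indices(constraints, segment_ids) \
        if constraints is not None else (np.empty((0, 2), int),) * 2

    folds = stratified_folds(records, n_folds,
                             seed if fold_seed is None else fold_seed)
    errors: list[float] = []
    held_out: dict[str, StrategyClass] = {}
    for f, test_idx in enumerate(folds):
        test_set = set(test_idx.tolist())
        train_records = [r for i, r in enumerate(records) if i not in test_set]
        train_rows = {pos[r.segment_id] for r in train_records
                      if r.segment_id in pos}
        ml_f, cl_f = _filter_constraints(ml, cl, train_rows)
        model = fit(features, (ml_f, cl_f), K, seed=seed * 1009 + f, **fit_kw)
        map_clusters_to_classes(model, features, train_records, segment_ids)
        n_err = 0
        n_tot = 0
        for i in test_idx:
            rec = records[i]
            row = pos.get(rec.segment_id)
            if row is None:
                continue
            cls = model.cluster_to_class.get(int(model.labels_[row]))
            pred = cls if cls is not None else StrategyClass.UNDEFINED
            held_out[rec.segment_id] = pred
            n_tot += 1
            if pred not in rec.labels:
                n_err += 1
        errors.append(n_err / n_tot if n_tot else 0.0)
    return CvResult(folds=n_folds, error=float(np.mean(errors)),
                    per_fold_errors=tuple(errors), held_out=held_out)
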