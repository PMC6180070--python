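import numpy as np
import pytest

from mwmtsa import LabelRecord, StrategyClass, derive_constraints
from mwmtsa import mpck


def blobs(seed, n_per=40, centres=((0, 0), (8, 8)), sd=0.7):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(c, sd, size=(n_per, 2)) for c in centres])
    return np.hstack([X, np.zeros((len(X), 6))])  # pad to 8 features


def lloyd_oracle(X, C0, max_iter=200):
    """Plain k-means from a given initialisation; empty clusters hold."""
    C = C0.copy()
    labels = None
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - C[None]) ** 2).sum(-1)
        new = np.argmin(d2, axis=1)
        if labels is not None and np.array_equal(new, labels):
            break
        labels = new
        for k in range(len(C)):
            m = labels == k
            if m.any():
                C[k] = X[m].mean(axis=0)
    return labels


def rec(seg_id, *codes):
    return LabelRecord(seg_id, frozenset(StrategyClass(c) for c in codes))


class TestFit:
    def test_reduces_to_kmeans_without_constraints_or_metrics(self):
        for seed in range(5):
            X = blobs(seed)
            model = mpck.fit(X, None, K=2, seed=seed, learn_metrics=False)
            C0 = mpck._init_centroids(X, 2, np.empty((0, 2), int),
                                      np.random.default_rng(seed))
            expected = lloyd_oracle(X, C0)
            np.testing.assert_array_equal(model.labels_, expected)

    def test_satisfied_cannot_link_changes_nothing(self):
        X = blobs(3)
        ids = [f"s{i}" for i in range(len(X))]
        plain = mpck.fit(X, None, K=2, seed=3, learn_metrics=False)
        # one cannot-link across the two blobs: already satisfied
        cs = derive_constraints([rec("s0", "TT"), rec(f"s{len(X) - 1}", "IC")],
                                seed=0)
        constrained = mpck.fit(X, cs, K=2, seed=3, segment_ids=ids,
                               learn_metrics=False)
        np.testing.assert_array_equal(constrained.labels_, plain.labels_)

    def test_must_link_overrides_geometry(self):
        """Exhaustive check: with a huge penalty the constrained pair is
        co-clustered in the best reachable 2-clustering."""
        X = np.array([[0.0, 0], [0.2, 0], [10.0, 0], [10.2, 0]])
        X = np.hstack([X, np.zeros((4, 6))])
        ids = ["a", "b", "c", "d"]
        cs = derive_constraints([rec("a", "TT"), rec("c", "TT")], seed=0)
        model = mpck.fit(X, cs, K=2, seed=1, segment_ids=ids,
                         learn_metrics=False, ml_penalty=1e6)
        assert model.labels_[0] == model.labels_[2]

    def test_objective_monotone_with_metric_learning(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            X = rng.normal(0, 1, size=(120, 8))
            ids = [f"s{i}" for i in range(len(X))]
            records = [rec(f"s{i}", "TT") for i in range(5)] + \
                      [rec(f"s{i}", "IC") for i in range(5, 10)]
            cs = derive_constraints(records, seed=seed)
            model = mpck.fit(X, cs, K=4, seed=seed, segment_ids=ids)
            hist = np.array(model.objective_history)
            assert np.all(np.diff(hist) <= 1e-8)

    def test_input_validation(self):
        X = blobs(0)
        with pytest.raises(ValueError, match="K"):
            mpck.fit(X, None, K=1, seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            mpck.fit(X[:3], None, K=5, seed=0)


class TestMappingAndPredict:
    def _fitted(self):
        X = blobs(7)
        ids = [f"s{i}" for i in range(len(X))]
        model = mpck.fit(X, None, K=2, seed=7)
        return X, ids, model

    def test_majority_tie_and_empty_rules(self):
        X, ids, model = self._fitted()
        k0 = int(model.labels_[0])          # cluster of the first blob
        k1 = 1 - k0
        # majority: two TT + one IC in cluster k0 -> TT; none in k1 -> None
        records = [rec(ids[0], "TT"), rec(ids[1], "TT"), rec(ids[2], "IC")]
        mpck.map_clusters_to_classes(model, X, records, ids)
        assert model.cluster_to_class[k0] is StrategyClass.TT
        assert model.cluster_to_class[k1] is None

        # exact tie -> unassigned
        records = [rec(ids[0], "TT"), rec(ids[1], "IC")]
        mpck.map_clusters_to_classes(model, X, records, ids)
        assert model.cluster_to_class[k0] is None

        # two-label records contribute half weight to each class
        records = [rec(ids[0], "TT"), rec(ids[1], "TT", "IC")]
        mpck.map_clusters_to_classes(model, X, records, ids)
        assert model.cluster_to_class[k0] is StrategyClass.TT

    def test_predict_own_label_and_undefined(self):
        X, ids, model = self._fitted()
        records = [rec(ids[0], "TT")]
        mpck.map_clusters_to_classes(model, X, records, ids)
        preds = mpck.predict(model, X)
        assert preds[0] is StrategyClass.TT
        k_other = 1 - int(model.labels_[0])
        other_rows = model.labels_ == k_other
        assert all(p is StrategyClass.UNDEFINED for p in preds[other_rows])

    def test_prediction_order_invariance(self):
        X, ids, model = self._fitted()
        records = [rec(ids[0], "TT"), rec(ids[-1], "IC")]
        mpck.map_clusters_to_classes(model, X, records, ids)
        perm = np.random.default_rng(0).permutation(len(X))
        direct = mpck.predict(model, X)[perm]
        permuted = mpck.predict(model, X[perm])
        assert all(a is b for a, b in zip(direct, permuted))

    def test_serialisation_round_trip(self):
        X, ids, model = self._fitted()
        mpck.map_clusters_to_classes(model, X, [rec(ids[0], "TT")], ids)
        back = mpck.MpckModel.from_dict(model.to_dict())
        np.testing.assert_allclose(back.centroids, model.centroids)
        assert back.cluster_to_class == model.cluster_to_class


class TestCrossValidate:
    def _setup(self, seed=0, n_per=30):
        rng = np.random.default_rng(seed)
        centres = rng.normal(0, 6, size=(4, 8))
        X = np.vstack([rng.normal(c, 0.5, size=(n_per, 8)) for c in centres])
        ids = [f"s{i}" for i in range(len(X))]
        codes = ["TT", "IC", "SC", "FS"]
        records = [rec(ids[c * n_per + j], codes[c])
                   for c in range(4) for j in range(8)]
        cs = derive_constraints(records, seed=seed)
        return X, ids, records, cs

    def test_separable_classes_near_zero_error(self):
        X, ids, records, cs = self._setup()
        cv = mpck.cross_validate(X, records, cs, K=6, seed=1,
                                 segment_ids=ids)
        assert cv.error < 0.1
        assert cv.error == pytest.approx(np.mean(cv.per_fold_errors))

    def test_random_labels_near_chance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, size=(300, 8))
        ids = [f"s{i}" for i in range(len(X))]
        codes = [c.value for c in StrategyClass
                 if c is not StrategyClass.UNDEFINED]
        records = [rec(ids[i], codes[rng.integers(9)]) for i in range(120)]
        cs = derive_constraints(records, max_pairs_per_class=100, seed=5)
        cv = mpck.cross_validate(X, records, cs, K=12, seed=5,
                                 segment_ids=ids)
        assert cv.error > 0.65   # chance floor is 8/9 minus mapping luck

    def test_determinism(self):
        X, ids, records, cs = self._setup()
        a = mpck.cross_validate(X, records, cs, K=5, seed=3, segment_ids=ids)
        b = mpck.cross_validate(X, records, cs, K=5, seed=3, segment_ids=ids)
        assert a.per_fold_errors == b.per_fold_errors

    def test_needs_ten_records(self):
        X, ids, records, cs = self._setup()
        with pytest.raises(ValueError, match="at least 10"):
            mpck.cross_validate(X, records[:5], cs, K=4, seed=0,
                                segment_ids=ids)
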