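from collections import Counter

import numpy as np
import pytest

from mwmtsa import StrategyClass, derive_constraints
from mwmtsa import ensemble as ens
from mwmtsa import mpck
from mwmtsa.labelling import LabelRecord
from mwmtsa.strategies import CLASS_INDEX, INDEX_CLASS, UNDEFINED_INDEX


def rec(seg_id, *codes):
    return LabelRecord(seg_id, frozenset(StrategyClass(c) for c in codes))


def fake_record(cv_error, K=10):
    model = mpck.MpckModel(K=K, centroids=np.zeros((K, 8)),
                           metric_weights=np.ones((K, 8)),
                           cluster_to_class={k: None for k in range(K)},
                           seed=0, objective=0.0)
    cv = mpck.CvResult(folds=10, error=cv_error,
                       per_fold_errors=(cv_error,) * 10, held_out={})
    return ens.ClassifierRecord(model=model, K=K, seed=0,
                                cv_error=cv_error, cv=cv)


class TestSelectStrong:
    def test_threshold_rule(self):
        pool = [fake_record(e) for e in (0.10, 0.24, 0.30)]
        e = ens.select_strong(pool, threshold=0.25, min_members=2)
        assert len(e) == 2

    def test_boundary_excluded(self):
        pool = [fake_record(0.25), fake_record(0.10)]
        e = ens.select_strong(pool, threshold=0.25, min_members=1)
        assert len(e) == 1 and e.members[0].cv_error == 0.10

    def test_all_weak_fails_with_labelling_diagnostic(self):
        pool = [fake_record(0.5) for _ in range(50)]
        with pytest.raises(ens.InsufficientLabellingError, match="labels"):
            ens.select_strong(pool, min_members=40)


def vote(*codes):
    """Column vector of member votes for a single segment."""
    return np.array([[CLASS_INDEX.get(StrategyClass(c), UNDEFINED_INDEX)]
                     for c in codes])


class TestMajorityVote:
    @pytest.mark.parametrize("codes,expected", [
        (("TT", "TT", "IC"), StrategyClass.TT),
        (("TT", "IC"), StrategyClass.UNDEFINED),
        (("--", "--", "CR"), StrategyClass.CR),
        (("--", "--"), StrategyClass.UNDEFINED),
    ])
    def test_rules(self, codes, expected):
        got = INDEX_CLASS[int(ens.majority_vote_codes(vote(*codes))[0])]
        assert got is expected

    def test_matches_exhaustive_count_oracle(self):
        """1000 random vote vectors against a Counter-based oracle."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n_members = int(rng.integers(1, 10))
            codes = rng.integers(0, UNDEFINED_INDEX + 1, size=(n_members, 1))
            got = int(ens.majority_vote_codes(codes)[0])
            counted = Counter(int(c) for c in codes[:, 0]
                              if c != UNDEFINED_INDEX)
            if not counted:
                expected = UNDEFINED_INDEX
            else:
                top = counted.most_common()
                if len(top) > 1 and top[0][1] == top[1][1]:
                    expected = UNDEFINED_INDEX
                else:
                    expected = top[0][0]
            assert got == expected

    def test_member_order_invariance(self):
        rng = np.random.default_rng(9)
        codes = rng.integers(0, UNDEFINED_INDEX + 1, size=(7, 40))
        base = ens.majority_vote_codes(codes)
        for _ in range(5):
            perm = rng.permutation(7)
            np.testing.assert_array_equal(
                ens.majority_vote_codes(codes[perm]), base)


class TestAgreement:
    def test_identical_and_disjoint(self):
        a = np.array([[0, 1, 2, 3], [0, 1, 2, 3]])
        assert ens.agreement_matrix(a).percentages[0, 1] == 100.0
        b = np.array([[0, 1, 2, 3], [1, 2, 3, 0]])
        assert ens.agreement_matrix(b).percentages[0, 1] == 0.0

    def test_three_classifier_brute_force(self):
        P = np.array([[0, 0, 1, 2],
                      [0, 1, 1, 2],
                      [2, 0, 1, 1]])
        m = ens.agreement_matrix(P)
        assert np.allclose(np.diag(m.percentages), 100.0)
        np.testing.assert_allclose(m.percentages[0, 1], 75.0)
        np.testing.assert_allclose(m.percentages[0, 2], 50.0)
        np.testing.assert_allclose(m.percentages[1, 2], 25.0)
        np.testing.assert_allclose(m.percentages, m.percentages.T)
        assert m.mean_off_diagonal == pytest.approx((75 + 50 + 25) / 3)


class TestUnclassifiedRate:
    def test_rates_and_boundary(self):
        ok = [StrategyClass.TT] * 100
        assert ens.unclassified_rate(ok) == (0.0, "OK")
        warn = [StrategyClass.UNDEFINED] * 3 + [StrategyClass.TT] * 97
        frac, status = ens.unclassified_rate(warn)
        assert frac == pytest.approx(0.03) and status == "WARN"
        fine = [StrategyClass.UNDEFINED] + [StrategyClass.TT] * 999
        assert ens.unclassified_rate(fine) == (0.001, "OK")


class TestBuildPool:
    def _data(self):
        rng = np.random.default_rng(2)
        centres = rng.normal(0, 6, size=(3, 8))
        X = np.vstack([rng.normal(c, 0.5, size=(25, 8)) for c in centres])
        ids = [f"s{i}" for i in range(len(X))]
        codes = ["TT", "IC", "SC"]
        records = [rec(ids[c * 25 + j], codes[c])
                   for c in range(3) for j in range(7)]
        return X, ids, records, derive_constraints(records, seed=2)

    def test_count_determinism_and_strength(self):
        X, ids, records, cs = self._data()
        pool = ens.build_pool(X, records, cs, K_range=range(4, 9), seed=6,
                              segment_ids=ids)
        assert len(pool) == 5
        assert [p.K for p in pool] == list(range(4, 9))
        again = ens.build_pool(X, records, cs, K_range=range(4, 9), seed=6,
                               segment_ids=ids)
        assert [p.cv_error for p in pool] == [p.cv_error for p in again]
        # well separated synthetic classes: far below the 8/9 chance level
        assert np.mean([p.cv_error for p in pool]) < 0.3

    def test_ensemble_cv_error_uses_shared_folds(self):
        X, ids, records, cs = self._data()
        pool = ens.build_pool(X, records, cs, K_range=range(4, 9), seed=6,
                              segment_ids=ids)
        team = ens.select_strong(pool, threshold=0.5, min_members=1)
        err = ens.ensemble_cv_error(team, records)
        assert 0.0 <= err <= np.mean([m.cv_error for m in team.members]) + 0.05

    def test_subsample_ensembles_seeded(self):
        X, ids, records, cs = self._data()
        pool = ens.build_pool(X, records, cs, K_range=range(4, 9), seed=6,
                              segment_ids=ids)
        team = ens.select_strong(pool, threshold=0.99, min_members=1)
        subs = ens.subsample_ensembles(team, n_ensembles=4, members_each=3,
                                       seed=1)
        assert len(subs) == 4 and all(len(s) == 3 for s in subs)
        again = ens.subsample_ensembles(team, n_ensembles=4, members_each=3,
                                        seed=1)
        assert [[m.K for m in s.members] for s in subs] == \
               [[m.K for m in s.members] for s in again]
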