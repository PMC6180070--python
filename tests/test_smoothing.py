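import math
from types import SimpleNamespace

import numpy as np
import pytest

from mwmtsa import (SmoothingConfig, StrategyClass, build_intervals,
                    class_weights, classify_interval,
                    classify_trajectory_intervals, count_transitions,
                    strategy_profile)
from mwmtsa.smoothing import segment_class_distribution
from mwmtsa.strategies import LABELLABLE
from _helpers import straight_trajectory

TT, IC, SC = StrategyClass.TT, StrategyClass.IC, StrategyClass.SC
UND = StrategyClass.UNDEFINED


def seg(start, end, centre, cls):
    """Minimal stand-in carrying the attributes the interval vote reads."""
    return SimpleNamespace(start_arc=start, end_arc=end,
                           centre=np.asarray(centre, float)), cls


def interval(start, end, centre):
    return SimpleNamespace(start_arc=start, end_arc=end,
                           centre=np.asarray(centre, float))


class TestBuildIntervals:
    def test_ten_even_intervals(self):
        traj = straight_trajectory(1000.0, n=1001)
        ivs = build_intervals(traj, R=100.0)
        assert len(ivs) == 10
        assert all(iv.length == pytest.approx(100.0, abs=0.51)
                   for iv in ivs)

    def test_remainder_kept_short(self):
        traj = straight_trajectory(250.0, n=251)
        lengths = [iv.length for iv in build_intervals(traj, R=100.0)]
        assert lengths == pytest.approx([100.0, 100.0, 50.0], abs=0.51)

    def test_short_path_single_interval(self):
        traj = straight_trajectory(40.0, n=41)
        ivs = build_intervals(traj, R=100.0)
        assert len(ivs) == 1 and ivs[0].length == pytest.approx(40.0)

    def test_abutting_without_overlap(self):
        traj = straight_trajectory(777.0, n=800)
        ivs = build_intervals(traj, R=100.0)
        for a, b in zip(ivs, ivs[1:]):
            assert b.start_arc == pytest.approx(a.end_arc)


class TestClassWeights:
    def test_symmetric_two_classes(self):
        w = class_weights({TT: 0.5, IC: 0.5})
        assert w[TT] == pytest.approx(0.5) and w[IC] == pytest.approx(0.5)

    def test_clipping_arithmetic(self):
        w = class_weights({TT: 0.8, IC: 0.2})
        assert w[TT] == pytest.approx(2 / 7)
        assert w[IC] == pytest.approx(5 / 7)

    def test_rare_class_clipped_up_before_inversion(self):
        w = class_weights({TT: 0.995, IC: 0.005})
        # both shares clip (0.5 and 0.01): rare class gets the larger weight
        assert w[IC] == pytest.approx((1 / 0.01) / (1 / 0.01 + 1 / 0.5))
        assert w[IC] > w[TT]

    def test_zero_share_excluded_and_all_zero_error(self):
        w = class_weights({TT: 1.0, IC: 0.0})
        assert IC not in w and w[TT] == pytest.approx(1.0)
        with pytest.raises(ValueError):
            class_weights({TT: 0.0})

    def test_distribution_helper(self):
        P = segment_class_distribution([TT, TT, IC, UND])
        assert P[TT] == pytest.approx(2 / 3)
        assert sum(P.values()) == pytest.approx(1.0)


class TestClassifyInterval:
    CFG = SmoothingConfig(sigma=100.0)

    def test_overlapping_segment_at_centre(self):
        s, c = seg(0, 250, (0, 0), TT)
        iv = interval(0, 100, (0, 0))
        ic = classify_interval(iv, [s], [c], self.CFG, {TT: 1.0})
        assert ic.strategy is TT
        assert ic.vote_sums[TT] == pytest.approx(1.0)

    def test_kernel_value_at_two_sigma_included(self):
        s, c = seg(0, 250, (200.0, 0), TT)   # d = 2*sigma exactly
        iv = interval(0, 100, (0, 0))
        ic = classify_interval(iv, [s], [c], self.CFG, {TT: 1.0})
        assert ic.strategy is TT
        assert ic.vote_sums[TT] == pytest.approx(math.exp(-2.0))
        assert round(ic.vote_sums[TT], 2) == 0.14

    def test_beyond_cutoff_excluded(self):
        s, c = seg(0, 250, (201.0, 0), TT)
        iv = interval(0, 100, (0, 0))
        ic = classify_interval(iv, [s], [c], self.CFG, {TT: 1.0})
        assert ic.strategy is UND and ic.vote_sums == {}

    def test_weights_break_distance_ties(self):
        a = seg(0, 120, (50.0, 0), TT)
        b = seg(40, 160, (-50.0, 0), IC)
        iv = interval(0, 100, (0, 0))
        ic = classify_interval(iv, [a[0], b[0]], [a[1], b[1]], self.CFG,
                               {TT: 0.7, IC: 0.3})
        assert ic.strategy is TT

    def test_non_overlapping_and_undefined_excluded(self):
        a = seg(500, 700, (0.0, 0), TT)      # no arc overlap
        b = seg(0, 100, (0.0, 0), UND)       # unclassified
        iv = interval(0, 100, (0, 0))
        ic = classify_interval(iv, [a[0], b[0]], [a[1], b[1]], self.CFG,
                               {TT: 1.0})
        assert ic.strategy is UND

    def test_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(77)
        cfg = SmoothingConfig(sigma=80.0)
        classes = list(LABELLABLE)
        for _ in range(20):
            n_seg = int(rng.integers(3, 12))
            segments, cls = [], []
            for _ in range(n_seg):
                a = float(rng.uniform(0, 400))
                s, c = seg(a, a + float(rng.uniform(30, 200)),
                           rng.uniform(-90, 90, 2),
                           classes[rng.integers(len(classes))])
                segments.append(s)
                cls.append(c)
            weights = {k: float(w) for k, w in
                       zip(classes, rng.dirichlet(np.ones(len(classes))))}
            iv = interval(float(rng.uniform(0, 300)),
                          float(rng.uniform(300, 500)),
                          rng.uniform(-90, 90, 2))
            got = classify_interval(iv, segments, cls, cfg, weights)
            # independent triple loop
            sums = {}
            for s, c in zip(segments, cls):
                if s.start_arc >= iv.end_arc or s.end_arc <= iv.start_arc:
                    continue
                d2 = float(np.sum((s.centre - iv.centre) ** 2))
                k = math.exp(-d2 / (2 * cfg.sigma ** 2))
                if k < cfg.kernel_cutoff:
                    continue
                sums[c] = sums.get(c, 0.0) + weights[c] * k
            if sums:
                best = max(sums.values())
                winners = [c for c, v in sums.items() if v == best]
                expected = winners[0] if len(winners) == 1 else UND
            else:
                expected = UND
            assert got.strategy is expected
            assert got.vote_sums.keys() == sums.keys()
            for c in sums:
                assert got.vote_sums[c] == pytest.approx(sums[c], abs=1e-12)

    def test_raising_sigma_keeps_single_class_winner(self):
        segments = [seg(0, 150, (30.0, 10.0), TT),
                    seg(50, 200, (60.0, -20.0), TT)]
        iv = interval(0, 100, (0, 0))
        for sigma in (50.0, 100.0, 400.0):
            ic = classify_interval(iv, [s for s, _ in segments],
                                   [c for _, c in segments],
                                   SmoothingConfig(sigma=sigma), {TT: 1.0})
            assert ic.strategy is TT


class TestTransitionsAndProfiles:
    def test_transition_counting(self):
        assert count_transitions([TT, TT, IC, IC, TT]) == 2
        assert count_transitions([TT, TT, TT]) == 0
        assert count_transitions([TT, UND, TT]) == 0
        assert count_transitions([TT, UND, IC]) == 1

    def test_short_trajectory_becomes_direct_finding(self, arena):
        traj = straight_trajectory(120.0, n=121)
        traj.short = True
        ics = classify_trajectory_intervals(traj, [], [], SmoothingConfig(),
                                            {}, R=100.0)
        assert len(ics) == 2
        assert all(ic.strategy is StrategyClass.DF for ic in ics)
        # a supplied whole-path label wins over the default
        ics = classify_trajectory_intervals(traj, [], [], SmoothingConfig(),
                                            {}, R=100.0,
                                            whole_path_label=TT)
        assert all(ic.strategy is TT for ic in ics)

    def test_profile_single_animal_all_one_class(self):
        traj = straight_trajectory(300.0, n=301)
        cls = [SimpleNamespace(interval=iv, strategy=TT, vote_sums={})
               for iv in build_intervals(traj, 100.0)]
        profile, trans = strategy_profile({traj: cls})
        row = profile.iloc[0]
        assert row["pct_TT"] == pytest.approx(100.0)
        assert row["pct_undefined"] == 0.0
        assert trans.iloc[0]["transitions"] == 0

    def test_profile_percentages_sum_to_100(self, arena):
        rng = np.random.default_rng(3)
        data = {}
        for i in range(4):
            traj = straight_trajectory(500.0 + 40 * i, n=600)
            traj.animal_id = f"a{i}"
            ivs = build_intervals(traj, 100.0)
            data[traj] = [SimpleNamespace(
                interval=iv,
                strategy=list(LABELLABLE)[rng.integers(9)],
                vote_sums={}) for iv in ivs]
        profile, _ = strategy_profile(data)
        pct_cols = [c for c in profile.columns
                    if c.startswith("pct_") and c != "pct_undefined"]
        sums = profile[pct_cols].sum(axis=1)
        np.testing.assert_allclose(sums, 100.0, atol=1e-9)
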