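import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import consensus_arena as ca
from consensus_arena.metrics import SupportCounts


def brute_delta_social(counts: dict, focal_site: str) -> int:
    best_alt = max(v for k, v in counts.items() if k != focal_site)
    return best_alt - counts[focal_site]


class TestDeltaSocial:
    def test_everyone_agrees_with_focal(self):
        sc = SupportCounts({"A": 9, "B": 0, "C": 0, "D": 0}, "A")
        assert ca.delta_social(sc) == -9

    def test_mixed_support(self):
        sc = SupportCounts({"A": 2, "B": 4, "C": 1, "D": 0}, "A")
        assert ca.delta_social(sc) == 2

    def test_focal_without_opinion_errors(self):
        with pytest.raises(ValueError):
            ca.delta_social(SupportCounts({"A": 1}, None))

    def test_exhaustive_against_brute_force_n_le_5(self):
        labels = list(ca.SITE_LABELS)
        for n_others in range(5):
            for assign in itertools.product(labels, repeat=n_others):
                counts = {lab: assign.count(lab) for lab in labels}
                for focal in labels:
                    sc = SupportCounts(counts, focal)
                    assert ca.delta_social(sc) == \
                        brute_delta_social(counts, focal)

    @given(st.lists(st.sampled_from("ABCD"), min_size=1, max_size=9),
           st.sampled_from("ABCD"))
    @settings(max_examples=200, deadline=None)
    def test_bounds_property(self, others, focal):
        counts = {lab: others.count(lab) for lab in ca.SITE_LABELS}
        ds = ca.delta_social(SupportCounts(counts, focal))
        n = len(others) + 1
        assert -(n - 1) <= ds <= n - 1


coords = st.floats(-75, 75, allow_nan=False)


class TestDistances:
    def test_two_players(self):
        assert ca.interplayer_distance([(0, 0), (10, 0)]) == pytest.approx(10)

    def test_equilateral_triangle(self):
        pts = [(0, 0), (5, 0), (2.5, 5 * math.sqrt(3) / 2)]
        assert ca.interplayer_distance(pts) == pytest.approx(5)

    def test_single_point_errors(self):
        with pytest.raises(ValueError):
            ca.interplayer_distance([(0, 0)])

    @given(st.lists(st.tuples(coords, coords), min_size=2, max_size=8))
    @settings(max_examples=200, deadline=None)
    def test_matches_double_loop_oracle(self, pts):
        naive = np.mean([math.dist(p, q)
                         for p, q in itertools.combinations(pts, 2)])
        assert ca.interplayer_distance(pts) == pytest.approx(naive, abs=1e-9)

    @given(st.lists(st.tuples(coords, coords), min_size=2, max_size=8),
           st.floats(-50, 50), st.floats(-50, 50),
           st.floats(-math.pi, math.pi))
    @settings(max_examples=100, deadline=None)
    def test_rigid_motion_invariance(self, pts, dx, dy, rot):
        c, s = math.cos(rot), math.sin(rot)
        moved = [(c * x - s * y + dx, s * x + c * y + dy) for x, y in pts]
        assert ca.interplayer_distance(moved) == \
            pytest.approx(ca.interplayer_distance(pts), rel=1e-9, abs=1e-9)

    def test_zero_iff_colocated(self):
        assert ca.interplayer_distance([(3, 3)] * 5) == 0.0
        assert ca.interplayer_distance([(3, 3), (3, 4)]) > 0

    def test_mean_distance_to_site(self):
        site = ca.Site("D", (40.0, 40.0), 15.0)
        assert ca.mean_distance_to_site([(40, 40)] * 4, site) == 0.0
        assert ca.mean_distance_to_site([(0, 0)], site) == \
            pytest.approx(40 * math.sqrt(2), abs=1e-9)

    @given(st.lists(st.tuples(coords, coords), min_size=1, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_mean_distance_oracle(self, pts):
        site = ca.Site("B", (-40.0, 40.0), 12.0)
        naive = np.mean([math.dist(p, site.center) for p in pts])
        assert ca.mean_distance_to_site(pts, site) == \
            pytest.approx(naive, abs=1e-9)


class TestComMetrics:
    def make(self, factory, positions):
        cfg = ca.TrialConfig(n_participants=len(positions))
        pos = {f"p{i:02d}": positions[i] for i in range(len(positions))}
        return factory(pos, cfg)

    def test_focal_at_com_distance_zero(self, hand_table_factory):
        cfg = ca.TrialConfig(n_participants=7)
        pos = {pid: [(0.0, 0.0)] * 3 for pid in cfg.participant_ids()}
        table = hand_table_factory(pos, cfg)
        assert ca.com_distance(table, "p00", 1.0) == 0.0

    def test_midpoint_of_two_clusters(self, hand_table_factory):
        cfg = ca.TrialConfig(n_participants=8)
        pids = cfg.participant_ids()
        pos = {pid: [(0.0, 0.0)] * 3 for pid in pids[:4]}
        pos.update({pid: [(10.0, 0.0)] * 3 for pid in pids[4:]})
        table = hand_table_factory(pos, cfg)
        assert ca.com_distance(table, "p00", 1.0) == pytest.approx(5.0)

    def test_com_distance_matches_oracle_on_simulated_trial(self, default_trial):
        table, _ = default_trial
        t1 = ca.resample_1hz(table)
        rng = np.random.default_rng(0)
        pids = t1.participant_ids()
        for t in rng.choice(t1.times(), size=5, replace=False):
            frame = t1.positions_at(t)
            com = frame[["x", "y"]].mean()
            for pid in rng.choice(pids, size=3, replace=False):
                naive = math.dist(frame.loc[pid, ["x", "y"]], com)
                assert ca.com_distance(t1, pid, float(t)) == \
                    pytest.approx(naive, abs=1e-9)

    def test_approach_speed_stationary_is_zero(self, hand_table_factory):
        cfg = ca.TrialConfig(n_participants=7)
        pos = {pid: [(float(i), 0.0) for i in range(4)]
               for pid in cfg.participant_ids()}
        pos["p00"] = [(50.0, 0.0)] * 4  # focal fixed, others drift
        table = hand_table_factory(pos, cfg)
        assert ca.approach_speed(table, "p00", 1.0) == pytest.approx(0.0)

    def test_approach_speed_head_on_at_com(self, hand_table_factory):
        # N=8, 7 others fixed at origin, focal runs at the COM at 8 m/s:
        # the COM co-moves at v/8, closing speed 8*(7/8), value 8*7 = 56
        cfg = ca.TrialConfig(n_participants=8)
        pids = cfg.participant_ids()
        pos = {pid: [(0.0, 0.0)] * 6 for pid in pids[1:]}
        pos[pids[0]] = [(64.0 - 8.0 * i, 0.0) for i in range(6)]
        table = hand_table_factory(pos, cfg)
        assert ca.approach_speed(table, pids[0], 2.0) == pytest.approx(56.0)

    def test_approach_speed_sign_flips_with_velocity(self, hand_table_factory):
        cfg = ca.TrialConfig(n_participants=8)
        pids = cfg.participant_ids()
        pos = {pid: [(0.0, 0.0)] * 6 for pid in pids[1:]}
        pos[pids[0]] = [(20.0 + 8.0 * i, 0.0) for i in range(6)]  # receding
        table = hand_table_factory(pos, cfg)
        assert ca.approach_speed(table, pids[0], 2.0) == pytest.approx(-56.0)

    def test_perpendicular_motion_zero_radial_speed(self, hand_table_factory):
        cfg = ca.TrialConfig(n_participants=7)
        pids = cfg.participant_ids()
        pos = {pid: [(0.0, 0.0)] * 5 for pid in pids[1:]}
        # focal circles the COM at constant radius
        r = 30.0
        pos[pids[0]] = [(r * math.cos(0.1 * i), r * math.sin(0.1 * i))
                        for i in range(5)]
        table = hand_table_factory(pos, cfg)
        # COM moves slightly with the focal, but radial speed is ~0
        assert abs(ca.approach_speed(table, pids[0], 2.0)) < 0.6
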