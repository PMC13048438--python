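import math

import numpy as np
import pandas as pd
import pytest

import consensus_arena as ca
from consensus_arena.simulate import AgentState, _BatchEngine, trial_seed


class TestHazard:
    def test_logistic_at_zero_is_half(self):
        p = ca.AgentParams(alpha=0.0)
        assert ca.switch_probability(p, 0.0, 0.0, 0.0) == pytest.approx(0.5)

    def test_degenerate_hazard_never_switches(self, global_config):
        p = ca.AgentParams.noiseless()
        assert ca.switch_probability(p, 5.0, 50.0, 0.0) == 0.0

    def test_informed_discount_removes_social_term(self):
        p = ca.AgentParams(alpha=-1.0, beta_ds=0.5, beta_dist=0.0,
                           beta_time=0.0, informed_social_discount=0.0)
        assert ca.switch_probability(p, 8.0, 0.0, 0.0, informed=True) == \
            pytest.approx(ca.switch_probability(p, 0.0, 0.0, 0.0))


class TestPerception:
    def test_zero_noise_global_equals_true_radii(self, global_config):
        state = AgentState(position=(0.0, 0.0), heading=0.0)
        params = ca.AgentParams(sigma_percept=0.0)
        rng = np.random.default_rng(0)
        out = ca.perceive_sites(state, params, global_config, rng)
        assert out == global_config.radii()

    def test_local_far_from_all_sites_unknown(self, local_config):
        state = AgentState(position=(0.0, 0.0), heading=0.0)  # 56.6 m away
        params = ca.AgentParams()
        out = ca.perceive_sites(state, params, local_config,
                                np.random.default_rng(0))
        assert all(v is None for v in out.values())

    def test_local_nearby_site_revealed(self, local_config):
        state = AgentState(position=(30.0, 30.0), heading=0.0)  # 14 m from D
        params = ca.AgentParams(sigma_percept=0.0)
        out = ca.perceive_sites(state, params, local_config,
                                np.random.default_rng(0))
        assert out["D"] == local_config.radii()["D"]
        assert out["A"] is None


class TestAgentStep:
    def test_straight_run_covers_speed_times_dt(self, global_config):
        # aligned agent advances 8 m along the diagonal in one 1 s tick
        h = math.atan2(1, 1)
        state = AgentState(position=(0.0, 0.0), heading=h,
                           current_target="D",
                           perceived_radii={k: v for k, v in
                                            global_config.radii().items()},
                           halt_point=(40.0, 40.0), commit_age=5)
        params = ca.AgentParams.noiseless()
        new = ca.agent_step(state, {}, params, global_config,
                            np.random.default_rng(0))
        d = math.dist(new.position, (0.0, 0.0))
        assert d == pytest.approx(8.0, abs=1e-9)
        assert math.atan2(new.position[1], new.position[0]) == pytest.approx(h)

    def test_never_switches_with_hazard_off(self, global_config):
        state = AgentState(position=(0.0, 0.0), heading=0.0,
                           current_target="A",
                           perceived_radii=global_config.radii(),
                           halt_point=(-40.0, -40.0), commit_age=10)
        params = ca.AgentParams.noiseless()
        for _ in range(5):
            state = ca.agent_step(state, {"B": 7}, params, global_config,
                                  np.random.default_rng(1))
        assert state.current_target == "A"

    def test_initial_choice_is_largest_perceived(self, global_config):
        state = AgentState(position=(0.0, 0.0), heading=0.0,
                           perceived_radii=global_config.radii())
        params = ca.AgentParams.noiseless()
        new = ca.agent_step(state, {}, params, global_config,
                            np.random.default_rng(0))
        assert new.current_target == global_config.correct_site

    def test_social_pull_can_override_size(self, global_config):
        state = AgentState(position=(0.0, 0.0), heading=0.0,
                           perceived_radii=global_config.radii())
        params = ca.AgentParams(sigma_percept=0.0, w_social=1.0,
                                alpha=-np.inf)
        new = ca.agent_step(state, {"A": 7}, params, global_config,
                            np.random.default_rng(0))
        assert new.current_target == "A"  # 12 + 7 > 15


class TestSimulateTrial:
    def test_noiseless_heads_to_largest_and_succeeds(self, noiseless_trial):
        _, outcome = noiseless_trial
        assert outcome["success"]
        assert outcome["consensus_site"] == "D"
        # start disc within 20 m of centre: travel time to D is 4.5..9.6 s
        assert 4.0 <= outcome["consensus_time"] <= 14.0

    def test_same_seed_identical_tables(self, global_config):
        p = ca.AgentParams()
        t1, o1 = ca.simulate_trial(global_config, p, seed=5)
        t2, o2 = ca.simulate_trial(global_config, p, seed=5)
        pd.testing.assert_frame_equal(t1.frames, t2.frames)
        assert o1 == o2

    def test_minimum_travel_geometry(self):
        # site centre is 40*sqrt(2) = 56.57 m from the arena centre:
        # an avatar there cannot arrive before 7.07 s at 8 m/s
        assert 40 * math.sqrt(2) / 8 == pytest.approx(7.071, abs=1e-3)

    def test_agents_stay_in_arena_and_under_speed_cap(self, default_trial):
        table, _ = default_trial
        cfg = table.config
        xy = table.frames[["x", "y"]].to_numpy()
        assert (np.abs(xy) <= cfg.arena_half_extent).all()
        for pid in table.participant_ids():
            sub = table.participant(pid)
            step = np.linalg.norm(np.diff(sub[["x", "y"]].to_numpy(), axis=0),
                                  axis=1)
            dh = np.diff(sub["heading"].to_numpy())
            dh = (dh + np.pi) % (2 * np.pi) - np.pi
            assert (step <= cfg.speed / cfg.sample_rate + 1e-6).all()
            assert (np.abs(dh) <= cfg.rot_rate / cfg.sample_rate + 1e-6).all()


class TestSimulateBatch:
    def test_cell_counts(self, global_config, local_config):
        tables, man = ca.simulate_batch([global_config, local_config],
                                        ca.AgentParams.noiseless(), 2, 9)
        assert len(tables) == 4
        assert len(man) == 4

    def test_manifest_reproducible(self, global_config):
        p = ca.AgentParams()
        _, m1 = ca.simulate_batch([global_config], p, 4, 17, record=False)
        _, m2 = ca.simulate_batch([global_config], p, 4, 17, record=False)
        pd.testing.assert_frame_equal(m1, m2)

    def test_trial_seed_below_2_31_and_stable(self):
        s = trial_seed(123, 5)
        assert s == trial_seed(123, 5)
        assert 0 <= s < 2 ** 32
        assert trial_seed(123, 6) != s

    def test_batching_matches_individual_simulation(self, global_config):
        # a trial's outcome depends only on its own seed, not the batch
        p = ca.AgentParams()
        tables, man = ca.simulate_batch([global_config], p, 3, 31)
        solo, o = ca.simulate_trial(global_config, p, int(man.seed[1]),
                                    trial_id=man.trial_id[1])
        pd.testing.assert_frame_equal(tables[1].frames, solo.frames)

    def test_zero_noise_zero_social_always_succeeds(self, global_config):
        _, man = ca.simulate_batch([global_config], ca.AgentParams.noiseless(),
                                   50, 77, record=False)
        assert man.success.all()

    def test_n_per_cell_validated(self, global_config):
        with pytest.raises(ValueError):
            ca.simulate_batch([global_config], ca.AgentParams(), 0, 1)


class TestInformedAgents:
    def test_informed_never_leave_correct_site(self):
        cfg = ca.TrialConfig(condition="informed_minority", difficulty="hard")
        eng = _BatchEngine(cfg, ca.AgentParams(), [trial_seed(5, i) for i in range(20)],
                           record=False, record_truth=True)
        eng.run()
        # informed agents are p00, p01 -> indices 0 and 1; their flips are
        # only ever toward the correct site, never away from it
        flips = eng.truth["flip"][:, :2, :]
        assert np.nansum(flips) == 0
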