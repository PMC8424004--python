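import math

import numpy as np
import pytest

from ablateq import rotors
from ablateq.env import (
    ACTIONS,
    AgentState,
    RewardConfig,
    SimOutcome,
    compute_reward,
    healthy_ablated_fraction,
    render_observation,
)

from _oracles import reward_table_oracle
from _policies import LatticePainter, toward_tip_action as toward_tip_policy


def agent_at(pos, run=0, ablated_shape=(20, 20)):
    return AgentState(position=pos, direction_run=run,
                      ablated=np.zeros(ablated_shape, bool), healthy_pixel_total=100)


class TestRewardEngine:
    CFG = RewardConfig()

    def test_matches_table_oracle_on_randomized_transitions(self):
        """Every reward component agrees exactly with an independent
        transcription of the published reward table (200 random cases)."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            prev = agent_at(tuple(rng.integers(0, 20, 2)), run=0)
            nxt = agent_at(tuple(rng.integers(0, 20, 2)), run=int(rng.integers(0, 9)))
            kind = rng.integers(0, 4)  # none / success / over / limit
            outcome = SimOutcome(
                success=kind == 1, over_ablation=kind == 2, step_limit=kind == 3,
                new_lesion_overlapped=bool(rng.random() < 0.5),
            )
            tips = None
            if rng.random() < 0.7:
                tips = [(float(rng.integers(0, 20)), float(rng.integers(0, 20)), 1)
                        for _ in range(rng.integers(1, 4))]
            ref = None
            if rng.random() < 0.7:
                ref = np.zeros((20, 20), bool)
                ref[rng.integers(0, 20, 5), rng.integers(0, 20, 5)] = True
            mode = "train" if rng.random() < 0.7 else "eval"
            action = int(rng.integers(0, 8))
            got = compute_reward(prev, action, nxt, outcome, tips, ref, self.CFG, mode)
            want = reward_table_oracle(prev, action, nxt, outcome, tips, ref, mode)
            assert got == want

    def test_plain_step_costs_one_point(self):
        prev, nxt = agent_at((5, 5)), agent_at((5, 14), run=1)
        r = compute_reward(prev, 2, nxt, SimOutcome(), tips=None,
                           reference_lesions=None, cfg=self.CFG, mode="train")
        assert r == -1.0

    def test_step_toward_tip_worth_fourteen(self):
        prev, nxt = agent_at((5, 5)), agent_at((5, 14), run=1)
        r = compute_reward(prev, 2, nxt, SimOutcome(), tips=[(5.0, 18.0, 1)],
                           reference_lesions=None, cfg=self.CFG, mode="train")
        assert r == -1.0 + 15.0

    def test_reablation_retreating_from_tip(self):
        prev, nxt = agent_at((5, 14)), agent_at((5, 5), run=1)
        r = compute_reward(prev, 6, nxt, SimOutcome(new_lesion_overlapped=True),
                           tips=[(5.0, 18.0, 1)], reference_lesions=None,
                           cfg=self.CFG, mode="train")
        assert r == -1.0 - 5.0 - 15.0

    def test_direction_run_penalty_grows_exponentially(self):
        prev = agent_at((5, 5))
        vals = []
        for n in (2, 3, 4):
            nxt = agent_at((5, 14), run=n)
            vals.append(compute_reward(prev, 2, nxt, SimOutcome(), None, None,
                                       self.CFG, "eval"))
        assert vals[0] == -1.0 - 0.01 * math.exp(2)
        assert vals[1] - vals[0] == pytest.approx(-0.01 * (math.exp(3) - math.exp(2)))
        assert vals[2] < vals[1] < vals[0]

    def test_shaping_terms_silent_in_eval_mode(self):
        prev, nxt = agent_at((5, 5)), agent_at((5, 14), run=1)
        ref = np.zeros((20, 20), bool)
        ref[10, 10] = True
        r = compute_reward(prev, 2, nxt, SimOutcome(), tips=[(5.0, 18.0, 1)],
                           reference_lesions=ref, cfg=self.CFG, mode="eval")
        assert r == -1.0

    def test_no_tip_suppresses_tip_term(self):
        prev, nxt = agent_at((5, 5)), agent_at((5, 14), run=1)
        r = compute_reward(prev, 2, nxt, SimOutcome(), tips=[],
                           reference_lesions=None, cfg=self.CFG, mode="train")
        assert r == -1.0


class TestHealthyAblatedFraction:
    def test_no_ablation_zero(self):
        healthy = np.ones((10, 10), bool)
        assert healthy_ablated_fraction(agent_at((5, 5), ablated_shape=(10, 10)), healthy) == 0.0

    def test_full_lesion_on_100_healthy_pixels(self):
        healthy = np.ones((10, 10), bool)
        a = agent_at((5, 5), ablated_shape=(10, 10))
        a.ablated[0:9, 0:9] = True  # one full 9x9 lesion
        assert healthy_ablated_fraction(a, healthy) == pytest.approx(0.81)

    def test_zero_healthy_rejected(self):
        a = agent_at((5, 5), ablated_shape=(10, 10))
        a.healthy_pixel_total = 0
        with pytest.raises(ValueError):
            healthy_ablated_fraction(a, np.zeros((10, 10), bool))


class TestEpisodes:
    def test_reset_deterministic_and_observation_contract(self, desk_env_factory):
        env = desk_env_factory(scenario_id=1, mode="train")
        a = env.reset()
        b = env.reset()
        assert a.shape == (75, 75, 3)
        assert a.dtype == np.float32
        assert a.min() >= 0.0 and a.max() <= 1.0
        assert np.array_equal(a, b)

    def test_success_episode_matches_quiescence(self, desk_env_factory):
        """The tip-chasing scripted policy terminates the rotor; the
        success terminal coincides exactly with tissue quiescence and the
        big positive reward."""
        env = desk_env_factory(scenario_id=1, mode="train")
        rng = np.random.default_rng(0)
        env.reset()
        rewards = []
        while not env.done:
            _, r, done, info = env.step(toward_tip_policy(env, rng))
            rewards.append(r)
            assert info["outcome"].success == rotors.is_quiescent(
                env.state, env.tissue, 0.2
            )
        res = env.result()
        assert res.terminal_cause == "success"
        assert rewards[-1] >= 420.0 - 1.0 - 5.0 - 0.01 * math.exp(res.steps)
        assert rewards[-1] > 300.0
        assert res.cumulative_reward == pytest.approx(sum(rewards))

    def test_step_limit_and_episode_cap(self, desk_env_factory):
        """An agent parked far from the rotor neither succeeds nor
        over-ablates: the episode ends at exactly 80 steps with the -50
        step-limit penalty."""
        env = desk_env_factory(scenario_id=1, mode="eval",
                               agent_start_offset=(0.32, 0.05))
        env.reset()
        rewards = []
        k = 0
        while not env.done:
            _, r, _, info = env.step(6 if k % 2 == 0 else 2)  # W, E, W, E ...
            rewards.append(r)
            k += 1
            assert env.agent.step_count <= 80
        res = env.result()
        assert res.terminal_cause == "step_limit"
        assert res.steps == 80
        assert rewards[-1] == -50.0 - 1.0 - 5.0  # limit + step + re-ablation

    def test_over_ablation_fires_at_first_crossing(self, desk_env_factory):
        """A serpentine sweep far from the rotor crosses the 40% healthy
        ablation cap; the first crossing step is terminal with -50."""
        env = desk_env_factory(scenario_id=2, mode="eval",
                               agent_start_offset=(-0.56, -0.387))  # lattice point
        env.reset()
        painter = LatticePainter(env, exclusion_radius=25.0)

        fractions = []
        while not env.done:
            _, r, done, info = env.step(painter())
            fractions.append(info["healthy_ablated_fraction"])
        res = env.result()
        assert res.terminal_cause == "over_ablation"
        assert fractions[-1] > 0.40
        assert all(f <= 0.40 for f in fractions[:-1])
        assert fractions == sorted(fractions)  # monotone non-decreasing

    def test_lesions_are_permanent_and_bounded(self, desk_env_factory):
        env = desk_env_factory(scenario_id=2, mode="eval")
        env.reset()
        rng = np.random.default_rng(1)
        prev_ablated = env.agent.ablated.copy()
        for _ in range(10):
            if env.done:
                break
            before = int(env.agent.ablated.sum())
            env.step(int(rng.integers(0, 8)))
            added = int(env.agent.ablated.sum()) - before
            assert added <= 81  # one 9x9 lesion at most
            assert (env.agent.ablated | prev_ablated).sum() == env.agent.ablated.sum()
            prev_ablated = env.agent.ablated.copy()
            assert (env.tissue.diffusion[env.agent.ablated] == 0.0).all()

    def test_blocked_moves_stay_put_but_cost(self, desk_env_factory):
        env = desk_env_factory(scenario_id=1, mode="eval")
        env.reset()
        env.agent.position = (1, 37)  # just inside the top edge, off-mask above
        _, r, _, _ = env.step(0)  # N: would leave the tissue
        assert env.agent.position == (1, 37)
        assert r <= -1.0

    def test_action_validation(self, desk_env_factory):
        env = desk_env_factory(scenario_id=1, mode="eval")
        env.reset()
        with pytest.raises(ValueError):
            env.step(8)
        with pytest.raises(ValueError):
            env.step(-1)

    def test_step_after_done_rejected(self, desk_env_factory):
        env = desk_env_factory(scenario_id=1, mode="eval")
        env.reset()
        env._done = True
        with pytest.raises(RuntimeError):
            env.step(0)

    def test_eval_mode_rewards_contain_no_shaping(self, desk_env_factory):
        """In eval mode the reward decomposes exactly into step,
        re-ablation, direction-run and terminal terms — nothing else —
        and the tip detector is never consulted."""
        env = desk_env_factory(scenario_id=2, mode="eval")
        env.reset()
        rng = np.random.default_rng(7)
        last_action, run = None, 0
        while not env.done:
            action = int(rng.integers(0, 8))
            run = run + 1 if action == last_action else 1
            last_action = action
            _, r, _, info = env.step(action)
            o = info["outcome"]
            expected = -1.0
            expected += 420.0 if o.success else 0.0
            expected += -50.0 if o.over_ablation else 0.0
            expected += -50.0 if o.step_limit else 0.0
            expected += -5.0 if o.new_lesion_overlapped else 0.0
            expected += -0.01 * math.exp(run) if run >= 2 else 0.0
            assert r == expected
        assert env.shaping_evaluations == 0

    def test_train_mode_counts_shaping_evaluations(self, desk_env_factory):
        env = desk_env_factory(scenario_id=1, mode="train")
        env.reset()
        env.step(0)
        env.step(2)
        assert env.shaping_evaluations == 2

    def test_full_diameter_line_always_ends_episode(self, desk_env_factory):
        """Ablating a straight line across the whole disk bisects it; the
        episode always terminates (no infinite episodes) and the rotor is
        extinguished."""
        env = desk_env_factory(scenario_id=1, mode="eval",
                               agent_start_offset=(-0.21, 0.0))
        env.reset()
        while not env.done:
            env.step(4)  # due south, one lesion-width at a time
        res = env.result()
        assert res.terminal_cause in ("success", "over_ablation", "step_limit")
        assert res.terminal_cause == "success"


class TestObservation:
    def test_resting_voltage_channel_uniform(self, desk_tissue):
        from ablateq import fenton_karma as fk

        obs = render_observation(fk.resting_state(desk_tissue), desk_tissue, None)
        assert (obs[:, :, 0] == 0.0).all()

    def test_structure_channel_distinguishes_tissue_classes(self, desk_fibrotic_tissue):
        from ablateq import fenton_karma as fk

        t = desk_fibrotic_tissue.copy()
        t.diffusion[37, 37] = 0.0  # ablate one healthy pixel
        obs = render_observation(fk.resting_state(t), t, None, d_healthy=0.05)
        ch = obs[:, :, 1]
        healthy_val = ch[t.mask & (t.diffusion == 0.05)][0]
        fibrotic_val = ch[t.fibrosis & (t.diffusion > 0)][0]
        ablated_val = ch[37, 37]
        outside_val = ch[~t.mask][0]
        assert len({healthy_val, fibrotic_val, ablated_val, outside_val}) == 4

    def test_agent_marker_visible(self, desk_tissue):
        from ablateq import fenton_karma as fk

        obs = render_observation(fk.resting_state(desk_tissue), desk_tissue, (37, 37))
        assert (obs[36:39, 36:39, 2] == 1.0).all()

    def test_identical_states_render_identically(self, desk_tissue):
        from ablateq import fenton_karma as fk

        s = fk.resting_state(desk_tissue)
        a = render_observation(s, desk_tissue, (10, 10))
        b = render_observation(s.copy(), desk_tissue, (10, 10))
        assert np.array_equal(a, b)
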