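import dataclasses

import numpy as np
import pytest
from scipy import stats

from ablateq.agent import (
    CheckpointError,
    DQNAgent,
    QNetworkSpec,
    ReplayBuffer,
    TrainingHyperparams,
    Transition,
    build_q_network,
    build_targets,
    decay_epsilon,
    learn_step,
    load_checkpoint,
    predict_q,
    save_checkpoint,
    select_action,
    sync_target,
)

TINY = QNetworkSpec(input_shape=(12, 12, 3), conv_filters=(4,), dense_width=8)


def tiny_agent(seed=0, **hp_over):
    hp = TrainingHyperparams(batch_size=8, replay_capacity=64, **hp_over)
    return DQNAgent(TINY, hp, seed=seed)


def rand_obs(rng, shape=(12, 12, 3)):
    return rng.random(shape).astype(np.float32)


class TestNetwork:
    def test_output_covers_eight_actions(self):
        agent = tiny_agent()
        q = predict_q(agent.online, rand_obs(np.random.default_rng(0)))
        assert q.shape == (8,)

    def test_twin_networks_identical_at_construction(self):
        agent = tiny_agent()
        rng = np.random.default_rng(1)
        for _ in range(3):
            obs = rand_obs(rng)
            assert np.array_equal(predict_q(agent.online, obs), predict_q(agent.target, obs))
        assert agent.online.n_params() == agent.target.n_params()

    def test_prediction_deterministic(self):
        agent = tiny_agent()
        obs = rand_obs(np.random.default_rng(2))
        assert np.array_equal(predict_q(agent.online, obs), predict_q(agent.online, obs))

    def test_same_seed_same_weights(self):
        a, b = tiny_agent(seed=7), tiny_agent(seed=7)
        for wa, wb in zip(a.online.get_weights(), b.online.get_weights()):
            assert np.array_equal(wa, wb)

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            build_q_network(
                QNetworkSpec(input_shape=(3, 3, 3), conv_filters=(4, 4)),
                np.random.default_rng(0),
            )

    def test_shape_mismatch_rejected(self):
        agent = tiny_agent()
        with pytest.raises(ValueError):
            predict_q(agent.online, np.zeros((12, 12), np.float32))


class TestActionSelection:
    def test_greedy_when_epsilon_zero(self):
        rng = np.random.default_rng(0)
        q = np.array([0.1, 2.0, -1.0, 0.5, 0.0, 0.0, 0.0, 0.0])
        assert all(select_action(q, 0.0, rng) == 1 for _ in range(50))

    def test_tie_breaks_to_lowest_index(self):
        rng = np.random.default_rng(0)
        assert select_action(np.zeros(8), 0.0, rng) == 0

    def test_full_exploration_uniform_over_other_actions(self):
        """At epsilon = 1 the argmax is never taken and the other seven
        actions are drawn uniformly (chi-square at p > 0.01)."""
        rng = np.random.default_rng(123)
        q = np.array([0.0, 3.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])  # argmax = 1
        draws = np.array([select_action(q, 1.0, rng) for _ in range(10_000)])
        assert (draws != 1).all()
        counts = np.bincount(draws, minlength=8)
        p = stats.chisquare(counts[[0, 2, 3, 4, 5, 6, 7]]).pvalue
        assert p > 0.01

    def test_epsilon_out_of_range_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            select_action(np.zeros(8), 1.5, rng)


class TestReplayBuffer:
    def tr(self, i):
        z = np.zeros((2, 2, 1), np.float32)
        return Transition(z, i % 8, float(i), z, False)

    def test_ring_buffer_evicts_oldest(self):
        buf = ReplayBuffer(4, np.random.default_rng(0))
        for i in range(5):
            buf.store(self.tr(i))
        rewards = {t.reward for t in buf._data}
        assert rewards == {1.0, 2.0, 3.0, 4.0}
        assert len(buf) == 4

    def test_oversampling_rejected(self):
        buf = ReplayBuffer(8, np.random.default_rng(0))
        buf.store(self.tr(0))
        with pytest.raises(ValueError):
            buf.sample(2)

    def test_seeded_sampling_reproducible(self):
        def sample_seq(seed):
            buf = ReplayBuffer(16, np.random.default_rng(seed))
            for i in range(16):
                buf.store(self.tr(i))
            return [[t.reward for t in buf.sample(4)] for _ in range(5)]

        assert sample_seq(5) == sample_seq(5)


class TestLearning:
    def test_targets_touch_only_taken_action(self):
        """Regression targets equal current predictions everywhere except
        the taken action's slot (gradient confinement)."""
        rng = np.random.default_rng(0)
        q_pred = rng.standard_normal((5, 8)).astype(np.float32)
        q_next = rng.standard_normal((5, 8)).astype(np.float32)
        actions = np.array([0, 3, 7, 2, 2])
        rewards = np.array([1.0, -1.0, 0.5, 0.0, 2.0], np.float32)
        terminals = np.array([1.0, 0.0, 1.0, 0.0, 0.0], np.float32)
        t = build_targets(q_pred, q_next, actions, rewards, terminals, gamma=0.9)
        for i in range(5):
            for a in range(8):
                if a == actions[i]:
                    want = rewards[i] + 0.9 * q_next[i].max() * (1 - terminals[i])
                    assert t[i, a] == pytest.approx(want, rel=1e-6)
                else:
                    assert t[i, a] == q_pred[i, a]

    def test_gamma_zero_terminal_converges_to_reward(self):
        """With gamma = 0 and a single repeated terminal transition the
        MSE fixed point is Q(s, a) = r."""
        agent = tiny_agent(learning_rate=0.02)
        obs = rand_obs(np.random.default_rng(3))
        tr = Transition(obs, 3, 1.0, obs, True)
        batch = [tr] * 8
        for _ in range(200):
            loss = learn_step(agent.online, agent.target, agent.optimizer, batch, gamma=0.0)
            assert loss >= 0.0
        q = predict_q(agent.online, obs)
        assert q[3] == pytest.approx(1.0, rel=0.05)

    def test_target_network_frozen_during_learning(self):
        agent = tiny_agent()
        before = agent.target.get_weights()
        obs = rand_obs(np.random.default_rng(4))
        batch = [Transition(obs, 1, 1.0, obs, False)] * 8
        learn_step(agent.online, agent.target, agent.optimizer, batch, gamma=0.9)
        for wa, wb in zip(before, agent.target.get_weights()):
            assert np.array_equal(wa, wb)

    def test_empty_minibatch_rejected(self):
        agent = tiny_agent()
        with pytest.raises(ValueError):
            learn_step(agent.online, agent.target, agent.optimizer, [], gamma=0.9)

    def test_sync_semantics(self):
        agent = tiny_agent()
        rng = np.random.default_rng(5)
        obs = rand_obs(rng)
        batch = [Transition(obs, 0, 1.0, obs, False)] * 8
        learn_step(agent.online, agent.target, agent.optimizer, batch, gamma=0.9)
        qo, qt = predict_q(agent.online, obs), predict_q(agent.target, obs)
        assert not np.array_equal(qo, qt)  # learning moved the online net
        sync_target(agent.online, agent.target)
        for _ in range(10):
            o = rand_obs(rng)
            assert np.array_equal(predict_q(agent.online, o), predict_q(agent.target, o))
        w1 = agent.target.get_weights()
        sync_target(agent.online, agent.target)  # idempotent
        for a, b in zip(w1, agent.target.get_weights()):
            assert np.array_equal(a, b)

    def test_two_state_task_learns_optimal_policy(self):
        """Tabular-oracle equivalence at tiny scale: on a two-observation
        task with +1/-1 terminal rewards the greedy policy recovers the
        optimal action in both states after 500 learn steps."""
        rng = np.random.default_rng(6)
        obs_a, obs_b = rand_obs(rng), rand_obs(rng)
        optimal = {0: 2, 1: 5}  # state index -> rewarded action
        agent = tiny_agent(learning_rate=0.01)
        buf = []
        for a in range(8):
            for s, obs in ((0, obs_a), (1, obs_b)):
                r = 1.0 if a == optimal[s] else -1.0
                buf.append(Transition(obs, a, r, obs, True))
        for _ in range(500):
            idx = rng.choice(len(buf), size=8, replace=False)
            learn_step(agent.online, agent.target, agent.optimizer,
                       [buf[i] for i in idx], gamma=0.95)
        assert int(np.argmax(predict_q(agent.online, obs_a))) == optimal[0]
        assert int(np.argmax(predict_q(agent.online, obs_b))) == optimal[1]


class TestBackprop:
    def test_analytic_gradients_match_finite_differences(self):
        """The hand-written conv/pool/dense backward pass agrees with
        central finite differences on a tiny network."""
        from ablateq.nn import mse_loss

        rng = np.random.default_rng(0)
        net = build_q_network(TINY, rng)
        x = rng.standard_normal((2, 12, 12, 3)).astype(np.float32)
        t = rng.standard_normal((2, 8)).astype(np.float32)
        pred = net.forward(x, train=False)
        _, grad = mse_loss(pred, t)
        net.backward(grad)
        analytic = [g.copy() for g in net.grads]
        for pi, par in enumerate(net.params):
            for _ in range(4):  # spot-check a few entries per tensor
                idx = tuple(int(rng.integers(0, s)) for s in par.shape)
                eps, old = 1e-3, par[idx]
                par[idx] = old + eps
                lp, _ = mse_loss(net.forward(x, train=False), t)
                par[idx] = old - eps
                lm, _ = mse_loss(net.forward(x, train=False), t)
                par[idx] = old
                numeric = (lp - lm) / (2 * eps)
                a = analytic[pi][idx]
                assert abs(numeric - a) <= 1e-2 * max(1.0, abs(numeric) + abs(a))


class TestEpsilonSchedule:
    HP = TrainingHyperparams(epsilon_start=1.0, epsilon_end=0.05, epsilon_decay=0.96)

    def test_boundary_values(self):
        assert decay_epsilon(self.HP, 0) == 1.0
        assert decay_epsilon(self.HP, 10_000) == pytest.approx(0.05, abs=1e-9)

    def test_monotone_non_increasing(self):
        eps = [decay_epsilon(self.HP, e) for e in range(200)]
        assert all(a >= b for a, b in zip(eps, eps[1:]))


class TestCheckpoints:
    def test_round_trip_preserves_predictions(self, tmp_path):
        agent = tiny_agent(seed=3)
        obs = rand_obs(np.random.default_rng(7))
        batch = [Transition(obs, 2, 1.0, obs, False)] * 8
        for _ in range(5):
            learn_step(agent.online, agent.target, agent.optimizer, batch, gamma=0.9)
        path = save_checkpoint(agent, tmp_path / "ck.npz")
        fresh = tiny_agent(seed=99)
        load_checkpoint(path, fresh)
        assert np.array_equal(predict_q(fresh.online, obs), predict_q(agent.online, obs))
        assert fresh.optimizer.t == agent.optimizer.t

    def test_incompatible_spec_rejected(self, tmp_path):
        agent = tiny_agent()
        path = save_checkpoint(agent, tmp_path / "ck.npz")
        other_spec = dataclasses.replace(TINY, input_shape=(16, 16, 3))
        other = DQNAgent(other_spec, TrainingHyperparams(batch_size=8), seed=0)
        with pytest.raises(CheckpointError):
            load_checkpoint(path, other)

    def test_missing_checkpoint(self, tmp_path):
        with pytest.raises(CheckpointError):
            load_checkpoint(tmp_path / "none.npz", tiny_agent())
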