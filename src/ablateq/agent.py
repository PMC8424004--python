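"""Deep Q-learning agent: twin CNNs, epsilon-greedy policy, replay.

Action values satisfy the Bellman optimality recursion
``Q(s, a) = R(s, a) + gamma * max_a' Q(s', a')``; the online network is
regressed by MSE towards targets built from a frozen copy (the target
network), which is re-synchronised to the online parameters every few
episodes for stability.  Only the taken action's output receives a
learning signal — the other outputs' regression targets equal the current
predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .nn import Adam, Conv2D, Dense, Dropout, Flatten, MaxPool2x2, Sequential, mse_loss

__all__ = [
    "QNetworkSpec",
    "TrainingHyperparams",
    "Transition",
    "ReplayBuffer",
    "build_q_network",
    "predict_q",
    "select_action",
    "learn_step",
    "sync_target",
    "decay_epsilon",
    "DQNAgent",
    "save_checkpoint",
    "load_checkpoint",
    "CheckpointError",
]


class CheckpointError(ValueError):
    """Checkpoint is missing, corrupt or incompatible with the agent."""


@dataclass(frozen=True)
class QNetworkSpec:
    """Architecture: repeated [conv 3x3 -> maxpool 2x2 -> dropout 0.2]
    blocks, a flatten, one hidden dense layer, and a linear output of size
    equal to the action space.

    The full-scale configuration is a 150x150x3 input with 256 filters per
    block; the sizes scale down for reduced-grid desk runs via the
    constructor arguments.
    """

    input_shape: tuple[int, int, int] = (150, 150, 3)
    conv_filters: tuple[int, ...] = (256, 256)
    kernel_size: int = 3
    dropout: float = 0.2
    dense_width: int = 64
    n_actions: int = 8


def build_q_network(spec: QNetworkSpec, rng: np.random.Generator) -> Sequential:
    """Construct the CNN; weights are drawn from ``rng`` (He init)."""
    h, w, c = spec.input_shape
    layers: list = []
    in_ch = c
    for f in spec.conv_filters:
        layers += [
            Conv2D(in_ch, f, spec.kernel_size, activation="relu", rng=rng),
            MaxPool2x2(),
            Dropout(spec.dropout, rng=np.random.default_rng(rng.integers(2**31))),
        ]
        h, w = (h - spec.kernel_size + 1) // 2, (w - spec.kernel_size + 1) // 2
        in_ch = f
    if h <= 0 or w <= 0:
        raise ValueError(f"input shape {spec.input_shape} too small for the conv stack")
    layers += [
        Flatten(),
        Dense(h * w * in_ch, spec.dense_width, activation="relu", rng=rng),
        Dense(spec.dense_width, spec.n_actions, activation=None, rng=rng),
    ]
    return Sequential(layers)


@dataclass(frozen=True)
class TrainingHyperparams:
    """Learning-loop knobs with their defaults.

    ``epsilon_decay`` is per-episode: eps(e) = end + (start - end) * decay^e.
    The default decay brings epsilon to ~0.1 by episode 500 at full scale.
    """

    gamma: float = 0.95
    epsilon_start: float = 1.0
    epsilon_end: float = 0.05
    epsilon_decay: float = 0.99413
    batch_size: int = 64
    replay_capacity: int = 20_000
    target_sync_every: int = 5  # episodes
    learning_rate: float = 1e-3
    learn_every: int = 1  # environment steps per learn step
    grad_clip_norm: float = 10.0  # global-norm clip on each minibatch gradient
    #: Rewards are multiplied by this before entering the replay buffer.
    #: The success reward (+420) is two orders of magnitude above the
    #: per-step costs; regressing raw values in float32 lets the Bellman
    #: bootstrap run away.  Scaling is policy-invariant (argmax of a
    #: positively scaled Q is unchanged).
    reward_scale: float = 1.0 / 42.0
    #: Stored rewards are clipped to [clip_low, clip_high] AFTER scaling.
    #: The same-direction penalty grows like exp(N) and reaches 1e32 for a
    #: long straight run; a single such transition destroys a float32
    #: network, and even moderate N values make the Q-target variance of
    #: any repeated action enormous (the run length is not part of the
    #: observation).  The bounds are asymmetric so the success reward is
    #: never clipped while the unbounded penalty saturates.
    reward_clip: tuple[float, float] | None = (-2.0, 11.0)

    def __post_init__(self) -> None:
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must lie in (0, 1)")
        if not 0 < self.epsilon_decay <= 1:
            raise ValueError("epsilon_decay must lie in (0, 1]")


@dataclass
class Transition:
    """The replay quintuple for one environment step."""

    state: np.ndarray
    action: int
    reward: float
    next_state: np.ndarray
    terminal: bool


class ReplayBuffer:
    """Uniform-sampling ring buffer of transitions."""

    def __init__(self, capacity: int, rng: np.random.Generator) -> None:
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self.rng = rng
        self._data: list[Transition] = []
        self._next = 0

    def store(self, tr: Transition) -> None:
        if len(self._data) < self.capacity:
            self._data.append(tr)
        else:
            self._data[self._next] = tr  # overwrite the oldest
        self._next = (self._next + 1) % self.capacity

    def sample(self, n: int) -> list[Transition]:
        """Uniform without replacement within one call; seeded by the rng."""
        if n > len(self._data):
            raise ValueError(f"cannot sample {n} of {len(self._data)} transitions")
        idx = self.rng.choice(len(self._data), size=n, replace=False)
        return [self._data[i] for i in idx]

    def __len__(self) -> int:
        return len(self._data)


def predict_q(network: Sequential, observation: np.ndarray) -> np.ndarray:
    """Action values for one observation; dropout inactive, deterministic."""
    obs = np.asarray(observation, dtype=np.float32)
    if obs.ndim != 3:
        raise ValueError(f"observation must be (H, W, C), got shape {obs.shape}")
    return network.forward(obs[None], train=False)[0]


def select_action(q_values: np.ndarray, epsilon: float, rng: np.random.Generator) -> int:
    """Epsilon-greedy: the argmax with probability 1 - epsilon, otherwise a
    uniform draw from the remaining actions.  Argmax ties break to the
    lowest index."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"epsilon must be in [0, 1], got {epsilon}")
    best = int(np.argmax(q_values))
    if rng.random() < epsilon:
        others = [a for a in range(len(q_values)) if a != best]
        return int(rng.choice(others))
    return best


def build_targets(
    q_pred: np.ndarray,
    q_next: np.ndarray,
    actions: np.ndarray,
    rewards: np.ndarray,
    terminals: np.ndarray,
    gamma: float,
) -> np.ndarray:
    """Bellman regression targets: current predictions everywhere except
    the taken action, which gets r (terminal) or r + gamma * max Q_target."""
    targets = q_pred.copy()
    y = rewards + gamma * q_next.max(axis=1) * (1.0 - terminals)
    targets[np.arange(len(actions)), actions] = y
    return targets


def learn_step(
    online: Sequential,
    target: Sequential,
    optimizer: Adam,
    minibatch: list[Transition],
    gamma: float,
    grad_clip_norm: float | None = 10.0,
) -> float:
    """One MSE regression step of the online network; the target network is
    only read.  Gradients are rescaled to ``grad_clip_norm`` (global norm)
    when they exceed it — the terminal rewards are two orders of magnitude
    larger than the per-step ones, and an unlucky minibatch can otherwise
    blow up the float32 optimiser state.  Returns the minibatch loss."""
    if not minibatch:
        raise ValueError("empty minibatch")
    states = np.stack([t.state for t in minibatch]).astype(np.float32)
    next_states = np.stack([t.next_state for t in minibatch]).astype(np.float32)
    actions = np.array([t.action for t in minibatch])
    rewards = np.array([t.reward for t in minibatch], dtype=np.float32)
    terminals = np.array([t.terminal for t in minibatch], dtype=np.float32)

    q_next = target.forward(next_states, train=False)
    q_pred = online.forward(states, train=True)
    targets = build_targets(q_pred, q_next, actions, rewards, terminals, gamma)
    loss, grad = mse_loss(q_pred, targets)
    online.backward(grad)
    grads = online.grads
    if grad_clip_norm is not None:
        norm = float(np.sqrt(sum(float((g * g).sum()) for g in grads)))
        if norm > grad_clip_norm:
            scale = np.float32(grad_clip_norm / norm)
            grads = [g * scale for g in grads]
    optimizer.step(grads)
    return loss


def sync_target(online: Sequential, target: Sequential) -> None:
    """Copy the online parameters into the target network (bit-equal)."""
    target.set_weights(online.get_weights())


def decay_epsilon(hp: TrainingHyperparams, episode: int) -> float:
    """Exploration rate for a training episode (non-increasing in episode)."""
    return hp.epsilon_end + (hp.epsilon_start - hp.epsilon_end) * hp.epsilon_decay**episode


class DQNAgent:
    """Twin-network Q-learning agent bound to one architecture spec."""

    def __init__(
        self,
        spec: QNetworkSpec,
        hp: TrainingHyperparams | None = None,
        seed: int = 0,
    ) -> None:
        self.spec = spec
        self.hp = hp or TrainingHyperparams()
        self.rng = np.random.default_rng(seed)
        self.online = build_q_network(spec, self.rng)
        self.target = build_q_network(spec, self.rng)
        sync_target(self.online, self.target)
        self.optimizer = Adam(self.online.params, lr=self.hp.learning_rate)
        self.buffer = ReplayBuffer(self.hp.replay_capacity, self.rng)
        self._step_count = 0

    def act(self, observation: np.ndarray, epsilon: float) -> int:
        return select_action(predict_q(self.online, observation), epsilon, self.rng)

    def observe(self, tr: Transition) -> float | None:
        """Store a transition (reward rescaled by ``hp.reward_scale``); run
        a learn step at the configured cadence once the buffer holds a full
        minibatch.  Returns the loss if a learn step ran."""
        r = tr.reward * self.hp.reward_scale
        if self.hp.reward_clip is not None:
            lo, hi = self.hp.reward_clip
            r = float(np.clip(r, lo, hi))
        if r != tr.reward:
            tr = Transition(tr.state, tr.action, r, tr.next_state, tr.terminal)
        self.buffer.store(tr)
        self._step_count += 1
        if (
            len(self.buffer) >= self.hp.batch_size
            and self._step_count % self.hp.learn_every == 0
        ):
            batch = self.buffer.sample(self.hp.batch_size)
            return learn_step(self.online, self.target, self.optimizer, batch,
                              self.hp.gamma, self.hp.grad_clip_norm)
        return None

    def end_episode(self, episode: int) -> None:
        """Target-network sync every ``target_sync_every`` episodes."""
        if (episode + 1) % self.hp.target_sync_every == 0:
            sync_target(self.online, self.target)

    def epsilon(self, episode: int) -> float:
        return decay_epsilon(self.hp, episode)


_CKPT_VERSION = 1


def save_checkpoint(agent: DQNAgent, path: str | Path) -> Path:
    """Write network parameters, optimiser state, hyperparams and rng state."""
    path = Path(path)
    opt = agent.optimizer.state()
    meta = {
        "format": "ablateq-checkpoint",
        "version": _CKPT_VERSION,
        "spec": asdict(agent.spec),
        "hyperparams": asdict(agent.hp),
        "opt_t": opt["t"],
        "opt_lr": opt["lr"],
        "rng_state": agent.rng.bit_generator.state,
    }
    arrays = {}
    for i, w in enumerate(agent.online.get_weights()):
        arrays[f"w{i}"] = w
    for i, m in enumerate(opt["m"]):
        arrays[f"m{i}"] = m
    for i, v in enumerate(opt["v"]):
        arrays[f"v{i}"] = v
    with open(path, "wb") as fh:
        np.savez(fh, _meta=np.frombuffer(json.dumps(meta).encode(), np.uint8), **arrays)
    return path


def load_checkpoint(path: str | Path, agent: DQNAgent) -> DQNAgent:
    """Restore a checkpoint into a compatible agent (in place).

    Rejects files whose architecture spec (input shape, action-space size,
    filters, dense width) does not match the agent's.
    """
    path = Path(path)
    if not path.exists():
        raise CheckpointError(f"no such checkpoint: {path}")
    try:
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["_meta"]).decode())
            n = len(agent.online.params)
            weights = [npz[f"w{i}"] for i in range(n)]
            m = [npz[f"m{i}"] for i in range(n)]
            v = [npz[f"v{i}"] for i in range(n)]
    except CheckpointError:
        raise
    except Exception as exc:
        raise CheckpointError(f"corrupt checkpoint {path}: {exc}") from None
    if meta.get("format") != "ablateq-checkpoint":
        raise CheckpointError(f"{path} is not an ablateq checkpoint")
    saved_spec = meta["spec"]
    mine = asdict(agent.spec)
    saved_spec = {k: tuple(v) if isinstance(v, list) else v for k, v in saved_spec.items()}
    if saved_spec != mine:
        raise CheckpointError(
            f"incompatible checkpoint: saved spec {saved_spec} != agent spec {mine}"
        )
    agent.online.set_weights(weights)
    sync_target(agent.online, agent.target)
    agent.optimizer.load_state({"t": meta["opt_t"], "lr": meta["opt_lr"], "m": m, "v": v})
    agent.rng.bit_generator.state = meta["rng_state"]
    return agent
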