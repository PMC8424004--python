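"""End-to-end training, evaluation and recurrence experiments.

Drives the episode loop of the ablation environment with the DQN agent:
tissues are synthesised in seed-disjoint train/test pools and shuffled,
the two training scenarios alternate across episodes, the exploration rate
decays per episode, the target network is synchronised every 5 episodes,
and every 50 episodes the block success rate is compared against the best
so far — the checkpoint is saved only on strict improvement.  Evaluation
re-runs the greedy policy (epsilon = 0, shaping rewards off) on unseen
tissues and stores each episode's lesion map, which the recurrence test
then challenges with cross-field re-initiation in four scenarios.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import fenton_karma as fk
from . import rotors
from .agent import DQNAgent, QNetworkSpec, TrainingHyperparams, Transition, save_checkpoint, load_checkpoint
from .env import AblationEnv, EnvConfig, RewardConfig
from .tissue import (
    SynthesisConfig,
    TissueModel,
    build_disk_geometry,
    build_diffusion_map,
    make_reference_lesions,
    synthesize_fibrosis,
)

__all__ = [
    "RunConfig",
    "MetricsBlock",
    "TrainResult",
    "EvalResult",
    "RecurrenceResult",
    "desk_profile",
    "make_tissue_pool",
    "train_agent",
    "evaluate_agent",
    "recurrence_test",
    "report_metrics",
]

log = logging.getLogger("ablateq")

METRICS_COLUMNS = [
    "episode", "scenario", "tissue_seed", "skipped", "success",
    "terminal_cause", "steps", "ablated_points", "reward", "epsilon",
]


@dataclass(frozen=True)
class RunConfig:
    """A fully serialisable description of one experiment.

    The full-scale defaults mirror the original study design (150-pixel
    disks at 0.3 mm, 900 training episodes, 100 test episodes); reduced
    configurations come from :func:`desk_profile`.
    """

    # tissue synthesis
    grid_size: int = 150
    pixel_spacing: float = 0.3
    fibrosis_fraction: float = 0.25
    correlation_length: float = 6.0
    n_tissues: int = 20
    n_test_tissues: int = 100
    # solver
    dt: float = 0.05
    param_set: str = "af"
    d_healthy: float = 0.05  # mm^2 per unit time
    d_fibrotic: float = 0.0075
    # episodes
    episodes: int = 900
    test_episodes: int = 100
    ablation_interval_ms: float = 10.0
    scenarios: tuple[int, ...] = (1, 2)
    lesion_size: int = 9
    step_length: int = 9
    agent_start_offset: tuple[float, float] = (0.12, 0.12)
    # agent
    conv_filters: tuple[int, ...] = (256, 256)
    dense_width: int = 64
    gamma: float = 0.95
    epsilon_start: float = 1.0
    epsilon_end: float = 0.05
    epsilon_decay: float = 0.99413
    batch_size: int = 64
    replay_capacity: int = 20_000
    learning_rate: float = 1e-3
    learn_every: int = 1
    target_sync_every: int = 5
    # bookkeeping
    eval_block: int = 50  # episodes per success-rate block
    seed: int = 0
    checkpoint_dir: str | None = None
    metrics_path: str | None = None

    def env_config(self) -> EnvConfig:
        return EnvConfig(
            ablation_interval_ms=self.ablation_interval_ms,
            lesion_size=self.lesion_size,
            step_length=self.step_length,
            agent_start_offset=self.agent_start_offset,
        )

    def solver_config(self) -> fk.SolverConfig:
        return fk.SolverConfig(dt=self.dt, dx=self.pixel_spacing)

    def fk_params(self) -> fk.FKParams:
        return fk.PARAM_SETS[self.param_set]

    def network_spec(self) -> QNetworkSpec:
        return QNetworkSpec(
            input_shape=(self.grid_size, self.grid_size, 3),
            conv_filters=self.conv_filters,
            dense_width=self.dense_width,
        )

    def hyperparams(self) -> TrainingHyperparams:
        return TrainingHyperparams(
            gamma=self.gamma,
            epsilon_start=self.epsilon_start,
            epsilon_end=self.epsilon_end,
            epsilon_decay=self.epsilon_decay,
            batch_size=self.batch_size,
            replay_capacity=self.replay_capacity,
            target_sync_every=self.target_sync_every,
            learning_rate=self.learning_rate,
            learn_every=self.learn_every,
        )


def desk_profile(seed: int = 0, episodes: int = 120, **overrides) -> RunConfig:
    """Reduced configuration that exercises the full loop on one CPU.

    The disk keeps its 45 mm physical size on a 75-pixel grid (0.6 mm
    pixels, dt = 0.1 ms, well inside the stability bound); the network
    shrinks to 8-filter blocks; fibrosis is lighter (15%, 4-pixel patches)
    because at 0.6 mm the slow fibrotic conduction is close to the
    discrete propagation limit.
    """
    cfg = RunConfig(
        grid_size=75,
        pixel_spacing=0.6,
        fibrosis_fraction=0.15,
        correlation_length=4.0,
        n_tissues=12,
        n_test_tissues=8,
        dt=0.1,
        param_set="af-short",
        episodes=episodes,
        test_episodes=16,
        conv_filters=(8, 8),
        dense_width=32,
        batch_size=32,
        replay_capacity=4000,
        gamma=0.8,  # short horizons: the shaping terms carry the signal
        learn_every=2,
        epsilon_end=0.1,
        epsilon_decay=0.95,  # ~0.15 by episode 60
        eval_block=50,
        seed=seed,
    )
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


@dataclass
class MetricsBlock:
    """Per-block success-rate summary (percent) plus ablation counts."""

    block_rates: list[float]
    best_rate: float
    min_rate: float
    max_rate: float
    final_rate: float
    avg_ablated_all: float
    avg_ablated_successful: float


@dataclass
class TrainResult:
    metrics: pd.DataFrame
    blocks: MetricsBlock | None
    best_checkpoint: Path | None
    agent: DQNAgent


@dataclass
class EvalResult:
    metrics: pd.DataFrame
    success_rate: float  # percent
    lesion_maps: dict[int, np.ndarray]  # episode index -> binary grid
    tissues: list[TissueModel]
    shaping_evaluations: int


@dataclass
class RecurrenceResult:
    table: pd.DataFrame  # tissue, scenario, initiated, sustained, prevented
    per_scenario: dict[int, float]  # prevention rate, percent
    overall: float  # percent of (tissue, scenario) pairs without AF


def make_tissue_pool(cfg: RunConfig, n: int, pool_seed: int) -> list[TissueModel]:
    """Synthesise ``n`` tissues with seeds drawn from ``pool_seed``.

    Train and test pools use different ``pool_seed`` values, making the
    tissue seed sets disjoint with overwhelming probability.
    """
    rng = np.random.default_rng(pool_seed)
    seeds = rng.integers(2**31, size=n)
    pool = []
    for s in seeds:
        scfg = SynthesisConfig(
            grid_size=cfg.grid_size,
            pixel_spacing=cfg.pixel_spacing,
            fibrosis_fraction=cfg.fibrosis_fraction,
            correlation_length=cfg.correlation_length,
            seed=int(s),
        )
        t = build_diffusion_map(
            synthesize_fibrosis(build_disk_geometry(scfg), scfg),
            cfg.d_healthy, cfg.d_fibrotic,
        )
        t.reference_lesions = make_reference_lesions(t)
        t.meta["tissue_seed"] = int(s)
        pool.append(t)
    return pool


def _episode_env(
    cache: dict,
    tissue: TissueModel,
    scenario_id: int,
    cfg: RunConfig,
    mode: str,
) -> AblationEnv:
    """Environments are cached per (tissue, scenario): repeated resets then
    reuse the deterministic rotor-initiation snapshot."""
    key = (id(tissue), scenario_id, mode)
    if key not in cache:
        cache[key] = AblationEnv(
            tissue,
            rotors.SCENARIOS[scenario_id],
            params=cfg.fk_params(),
            solver=cfg.solver_config(),
            cfg=cfg.env_config(),
            mode=mode,
        )
    return cache[key]


def _run_episode(env: AblationEnv, policy, max_retries: int = 1) -> dict | None:
    """Reset (re-initialising once if the rotor died during settling) and
    play one episode.  Returns None if the tissue cannot host the rotor."""
    obs = None
    for attempt in range(max_retries + 1):
        try:
            obs = env.reset(reuse_initiation=attempt == 0)
        except rotors.InitiationError:
            return None
        if not rotors.is_quiescent(env.state, env.tissue):
            break
    else:
        return None
    transitions = []
    try:
        while not env.done:
            action = policy(obs)
            nxt, reward, done, info = env.step(action)
            transitions.append(Transition(obs, action, reward, nxt, done))
            obs = nxt
    except fk.NumericalBlowUpError as exc:  # pragma: no cover - defensive
        log.warning("episode aborted: %s", exc)
        return None
    res = env.result()
    return {
        "success": res.success,
        "terminal_cause": res.terminal_cause,
        "steps": res.steps,
        "ablated_points": res.ablated_points,
        "reward": res.cumulative_reward,
        "lesion_map": res.lesion_map,
        "transitions": transitions,
    }


def _summarise_blocks(df: pd.DataFrame, block: int) -> MetricsBlock | None:
    played = df[~df["skipped"]]
    if played.empty:
        return None
    rates = []
    for start in range(0, int(df["episode"].max()) + 1, block):
        blk = played[(played["episode"] >= start) & (played["episode"] < start + block)]
        if len(blk):
            rates.append(100.0 * blk["success"].mean())
    succ = played[played["success"]]
    return MetricsBlock(
        block_rates=rates,
        best_rate=max(rates) if rates else float("nan"),
        min_rate=min(rates) if rates else float("nan"),
        max_rate=max(rates) if rates else float("nan"),
        final_rate=rates[-1] if rates else float("nan"),
        avg_ablated_all=float(played["ablated_points"].mean()),
        avg_ablated_successful=float(succ["ablated_points"].mean()) if len(succ) else float("nan"),
    )


def train_agent(cfg: RunConfig, policy: str = "dqn") -> TrainResult:
    """Train for ``cfg.episodes`` episodes; returns metrics and the best
    checkpoint (saved only on strict block-success-rate improvement).

    ``policy='random'`` runs the identical schedule with uniform random
    actions and no learning — the paired exploration baseline.
    """
    if policy not in ("dqn", "random"):
        raise ValueError(f"unknown policy {policy!r}")
    rng = np.random.default_rng(cfg.seed)
    pool = make_tissue_pool(cfg, cfg.n_tissues, pool_seed=cfg.seed * 2 + 1)
    agent = DQNAgent(cfg.network_spec(), cfg.hyperparams(), seed=cfg.seed + 1)
    ckpt_dir = Path(cfg.checkpoint_dir) if cfg.checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)

    env_cache: dict = {}
    rows: list[dict] = []
    order: list[int] = []
    best_rate = -1.0
    best_ckpt: Path | None = None

    for ep in range(cfg.episodes):
        if not order:
            order = list(rng.permutation(len(pool)))
        tissue = pool[order.pop()]
        scenario_id = cfg.scenarios[ep % len(cfg.scenarios)]
        env = _episode_env(env_cache, tissue, scenario_id, cfg, mode="train")
        eps = agent.epsilon(ep)

        if policy == "random":
            def act(obs):
                return int(rng.integers(env.n_actions))
        else:
            def act(obs):
                return agent.act(obs, eps)

        out = _run_episode(env, act)
        row = {
            "episode": ep, "scenario": scenario_id,
            "tissue_seed": tissue.meta.get("tissue_seed", -1),
            "skipped": out is None, "success": bool(out and out["success"]),
            "terminal_cause": out["terminal_cause"] if out else "skipped",
            "steps": out["steps"] if out else 0,
            "ablated_points": out["ablated_points"] if out else 0,
            "reward": out["reward"] if out else 0.0,
            "epsilon": eps,
        }
        rows.append(row)
        if out is None:
            log.info("episode %d skipped (rotor not sustained on tissue %s)",
                     ep, row["tissue_seed"])
        elif policy == "dqn":
            for tr in out["transitions"]:
                agent.observe(tr)
            agent.end_episode(ep)

        if (ep + 1) % cfg.eval_block == 0:
            df = pd.DataFrame(rows, columns=METRICS_COLUMNS)
            blk = df[(df["episode"] > ep - cfg.eval_block) & (~df["skipped"])]
            rate = 100.0 * blk["success"].mean() if len(blk) else 0.0
            if rate > best_rate:
                best_rate = rate
                if ckpt_dir and policy == "dqn":
                    best_ckpt = save_checkpoint(agent, ckpt_dir / f"best_ep{ep + 1}.npz")
            log.info("episode %d: block success %.1f%% (best %.1f%%)", ep + 1, rate, best_rate)

    df = pd.DataFrame(rows, columns=METRICS_COLUMNS)
    if cfg.metrics_path:
        report_metrics(df, cfg.metrics_path)
    return TrainResult(
        metrics=df,
        blocks=_summarise_blocks(df, cfg.eval_block),
        best_checkpoint=best_ckpt,
        agent=agent,
    )


def evaluate_agent(
    cfg: RunConfig,
    agent: DQNAgent | None = None,
    checkpoint: str | Path | None = None,
    policy=None,
) -> EvalResult:
    """Greedy evaluation on unseen tissues; shaping rewards are off.

    Exactly one of ``agent``, ``checkpoint`` or ``policy`` (a callable
    observation -> action, for scripted strategies) must be supplied.
    Lesion maps of every finished episode are collected for the recurrence
    test.
    """
    if sum(x is not None for x in (agent, checkpoint, policy)) != 1:
        raise ValueError("supply exactly one of agent, checkpoint or policy")
    if checkpoint is not None:
        agent = DQNAgent(cfg.network_spec(), cfg.hyperparams(), seed=cfg.seed + 1)
        load_checkpoint(checkpoint, agent)
    pool = make_tissue_pool(cfg, cfg.n_test_tissues, pool_seed=cfg.seed * 2 + 2)
    env_cache: dict = {}
    rows, lesion_maps, tissues = [], {}, []
    shaping = 0
    for ep in range(cfg.test_episodes):
        tissue = pool[ep % len(pool)]
        scenario_id = cfg.scenarios[ep % len(cfg.scenarios)]
        env = _episode_env(env_cache, tissue, scenario_id, cfg, mode="eval")
        act = policy if policy is not None else (lambda obs: agent.act(obs, 0.0))
        out = _run_episode(env, act)
        shaping += env.shaping_evaluations
        rows.append({
            "episode": ep, "scenario": scenario_id,
            "tissue_seed": tissue.meta.get("tissue_seed", -1),
            "skipped": out is None, "success": bool(out and out["success"]),
            "terminal_cause": out["terminal_cause"] if out else "skipped",
            "steps": out["steps"] if out else 0,
            "ablated_points": out["ablated_points"] if out else 0,
            "reward": out["reward"] if out else 0.0,
            "epsilon": 0.0,
        })
        if out is not None:
            lesion_maps[ep] = out["lesion_map"]
            tissues.append(tissue)
        else:
            tissues.append(tissue)
    df = pd.DataFrame(rows, columns=METRICS_COLUMNS)
    played = df[~df["skipped"]]
    rate = 100.0 * played["success"].mean() if len(played) else float("nan")
    if cfg.metrics_path:
        report_metrics(df, cfg.metrics_path)
    return EvalResult(
        metrics=df, success_rate=float(rate), lesion_maps=lesion_maps,
        tissues=tissues, shaping_evaluations=shaping,
    )


def apply_lesions(tissue: TissueModel, lesion_map: np.ndarray) -> TissueModel:
    """Non-conductive catheter-ablation lesions burned into a tissue copy."""
    out = tissue.copy()
    out.diffusion[np.asarray(lesion_map, bool) & out.mask] = 0.0
    return out


def recurrence_test(
    tissues: list[TissueModel],
    lesion_maps: list[np.ndarray],
    cfg: RunConfig,
    scenario_ids: tuple[int, ...] = (1, 2, 3, 4),
    horizon_ms: float = 1500.0,
    settle_ms: float = 100.0,
) -> RecurrenceResult:
    """Attempt cross-field re-initiation on ablated tissues (no learning).

    For every (tissue, scenario) pair the lesions are applied (D = 0), the
    rotor-initiation protocol is run, and the pair counts as *prevented*
    when no sustained activity remains — including the case where the
    lesions block the plane wave outright.
    """
    if len(tissues) == 0:
        raise ValueError("recurrence test on an empty tissue set is undefined")
    if len(tissues) != len(lesion_maps):
        raise ValueError("one lesion map per tissue required")
    params = cfg.fk_params()
    solver = fk.SolverConfig(dt=cfg.dt, dx=cfg.pixel_spacing)
    rows = []
    for ti, (tissue, lesions) in enumerate(zip(tissues, lesion_maps)):
        ablated = apply_lesions(tissue, lesions)
        for sid in scenario_ids:
            scen = rotors.SCENARIOS[sid]
            initiated, sustained = True, False
            try:
                st = fk.resting_state(ablated)
                st = rotors.apply_cross_field(st, ablated, params, solver, scen)
                st = fk.run(st, ablated, params, solver, settle_ms)
                sustained = rotors.is_sustained(
                    st, ablated, params, solver, horizon_ms=horizon_ms
                )
            except rotors.InitiationError:
                initiated = False
            rows.append({
                "tissue": ti, "scenario": sid, "initiated": initiated,
                "sustained": sustained, "prevented": not sustained,
            })
    table = pd.DataFrame(rows)
    per_scenario = {
        int(s): 100.0 * grp["prevented"].mean()
        for s, grp in table.groupby("scenario")
    }
    overall = 100.0 * table["prevented"].mean()
    return RecurrenceResult(table=table, per_scenario=per_scenario, overall=float(overall))


def report_metrics(df: pd.DataFrame, path: str | Path, block: int = 50) -> str:
    """Write the per-episode metrics CSV and return a text summary."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    blocks = _summarise_blocks(df, block)
    if blocks is None:
        return f"no completed episodes; wrote {path}"
    lines = [
        f"episodes: {len(df)} ({int(df['skipped'].sum())} skipped)",
        f"per-{block}-episode success rate: min {blocks.min_rate:.1f}%, "
        f"max {blocks.max_rate:.1f}%, final {blocks.final_rate:.1f}%",
        f"average ablated points: {blocks.avg_ablated_all:.1f} (all), "
        f"{blocks.avg_ablated_successful:.1f} (successful episodes)",
        f"metrics written to {path}",
    ]
    return "\n".join(lines)
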