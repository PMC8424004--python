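"""Episodic ablation environment.

One episode: a rotor is initiated on a 2D atrial tissue; an ablating agent
then moves over the tissue in 8 compass directions, at every step burning a
9x9-pixel lesion (diffusion set to 0 there, permanently for the episode)
and letting the simulation advance by the ablation interval (10 ms by
default, 50 ms optional).  The episode ends in success when the voltage
drops below 0.2 on all conductive non-ablated tissue, or in failure when
40% of the healthy tissue has been ablated or 80 steps have been taken.

The reward is a sum of independent components:

===============================================  =======  ========
event                                             points  terminal
===============================================  =======  ========
successful ablation (all u < 0.2)                   +420   yes
40% of healthy tissue ablated                        -50   yes
80 steps taken                                       -50   yes
each step taken                                       -1   no
ablating already ablated tissue                       -5   no
N-th consecutive move in the same direction    -0.01*e^N   no
moving closer to / further from the rotor tip        +/-15  no
moving closer to / further from reference lesions    +/-15  no
===============================================  =======  ========

The two proximity terms shape exploration during training only; in
evaluation mode they are disabled and rotor tips are never consulted.
The environment follows the conventional episodic reset/step/render API.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import fenton_karma as fk
from . import rotors
from .tissue import TissueModel

__all__ = [
    "ACTIONS",
    "RewardConfig",
    "EnvConfig",
    "AgentState",
    "SimOutcome",
    "EpisodeResult",
    "AblationEnv",
    "compute_reward",
    "healthy_ablated_fraction",
    "render_observation",
    "initiate_rotor",
]

#: The 8 compass moves as (d_row, d_col) unit offsets, index = action id.
ACTIONS: tuple[tuple[int, int], ...] = (
    (-1, 0),   # 0 N
    (-1, 1),   # 1 NE
    (0, 1),    # 2 E
    (1, 1),    # 3 SE
    (1, 0),    # 4 S
    (1, -1),   # 5 SW
    (0, -1),   # 6 W
    (-1, -1),  # 7 NW
)


@dataclass(frozen=True)
class RewardConfig:
    """All reward constants and termination thresholds."""

    success_reward: float = 420.0
    over_ablation_penalty: float = -50.0
    step_limit_penalty: float = -50.0
    per_step_penalty: float = -1.0
    re_ablation_penalty: float = -5.0
    direction_penalty_coeff: float = 0.01
    direction_penalty_negative: bool = True  # text says penalty; table prints magnitude
    tip_approach_reward: float = 15.0
    tip_retreat_reward: float = -15.0
    lesion_approach_reward: float = 15.0
    lesion_retreat_reward: float = -15.0
    max_healthy_ablated_fraction: float = 0.40
    max_steps: int = 80
    quiescence_threshold: float = 0.2
    charge_step_on_terminal: bool = True  # the -1 accrues on terminal steps too


@dataclass(frozen=True)
class EnvConfig:
    """Episode mechanics: lesion geometry, cadence and rotor settling."""

    ablation_interval_ms: float = 10.0  # 50 ms is the slow-ablation variant
    lesion_size: int = 9  # side of the square lesion, pixels
    step_length: int = 9  # agent displacement per move, pixels
    agent_start_offset: tuple[float, float] = (0.08, 0.08)  # grid fractions
    settle_ms: float = 100.0  # time between wave break and first action
    tip_tau_ms: float = rotors.TIP_TAU_MS


@dataclass
class AgentState:
    """Mutable per-episode agent bookkeeping."""

    position: tuple[int, int]
    step_count: int = 0
    direction_run: int = 0
    last_action: int | None = None
    ablated: np.ndarray | None = None
    healthy_pixel_total: int = 0


@dataclass(frozen=True)
class SimOutcome:
    """What the simulated interval and lesion placement produced."""

    success: bool = False
    over_ablation: bool = False
    step_limit: bool = False
    new_lesion_overlapped: bool = False


@dataclass
class EpisodeResult:
    success: bool
    steps: int
    ablated_points: int
    cumulative_reward: float
    lesion_map: np.ndarray
    terminal_cause: str  # 'success' | 'over_ablation' | 'step_limit'


def healthy_ablated_fraction(agent: AgentState, healthy: np.ndarray) -> float:
    """Fraction of initially healthy (non-fibrotic) tissue now ablated."""
    if agent.healthy_pixel_total <= 0:
        raise ValueError("tissue has no healthy pixels")
    return float((agent.ablated & healthy).sum()) / agent.healthy_pixel_total


def _nearest_distance(pos: tuple[float, float], points: np.ndarray) -> float | None:
    """Euclidean pixel distance from pos to the nearest of an (n,2) array."""
    if points.size == 0:
        return None
    d = np.hypot(points[:, 0] - pos[0], points[:, 1] - pos[1])
    return float(d.min())


def compute_reward(
    prev: AgentState,
    action: int,
    nxt: AgentState,
    outcome: SimOutcome,
    tips: list[tuple[float, float, int]] | None,
    reference_lesions: np.ndarray | None,
    cfg: RewardConfig,
    mode: str = "train",
) -> float:
    """Exact sum of the applicable reward components for one transition.

    Pure function of its arguments.  The tip and reference-lesion proximity
    terms apply in training mode only; the tip term is suppressed when no
    tip is detectable, and either proximity term is zero when the distance
    did not change.
    """
    r = 0.0
    if outcome.success:
        r += cfg.success_reward
    if outcome.over_ablation:
        r += cfg.over_ablation_penalty
    if outcome.step_limit:
        r += cfg.step_limit_penalty
    terminal = outcome.success or outcome.over_ablation or outcome.step_limit
    if not terminal or cfg.charge_step_on_terminal:
        r += cfg.per_step_penalty
    if outcome.new_lesion_overlapped:
        r += cfg.re_ablation_penalty
    if nxt.direction_run >= 2:
        mag = cfg.direction_penalty_coeff * math.exp(nxt.direction_run)
        r += -mag if cfg.direction_penalty_negative else mag
    if mode == "train":
        if tips:
            pts = np.asarray([(t[0], t[1]) for t in tips], dtype=float)
            d0 = _nearest_distance(prev.position, pts)
            d1 = _nearest_distance(nxt.position, pts)
            if d1 < d0:
                r += cfg.tip_approach_reward
            elif d1 > d0:
                r += cfg.tip_retreat_reward
        if reference_lesions is not None and reference_lesions.any():
            pts = np.argwhere(reference_lesions).astype(float)
            d0 = _nearest_distance(prev.position, pts)
            d1 = _nearest_distance(nxt.position, pts)
            if d1 < d0:
                r += cfg.lesion_approach_reward
            elif d1 > d0:
                r += cfg.lesion_retreat_reward
    return r


def render_observation(
    state: fk.EPState,
    tissue: TissueModel,
    agent_pos: tuple[int, int] | None,
    d_healthy: float | None = None,
) -> np.ndarray:
    """Three-channel image observation in [0, 1], fixed normalisation.

    Channel 0: voltage u scaled by the model's overshoot bound 1.1.
    Channel 1: structure — 0 outside tissue, 1 healthy, D/D_healthy on
    fibrosis (~0.15), 0.6 on ablated lesions.
    Channel 2: fast gate v scaled to [0, 0.5], with a bright 3x3 marker at
    the agent position.
    """
    h, w = tissue.mask.shape
    obs = np.zeros((h, w, 3), dtype=np.float32)
    obs[:, :, 0] = np.clip(state.u / 1.1, 0.0, 1.0)
    if d_healthy is None:
        d_healthy = float(tissue.diffusion.max(initial=0.0)) or 1.0
    struct = np.where(tissue.mask, tissue.diffusion / d_healthy, 0.0)
    struct = np.where(tissue.mask & (tissue.diffusion == 0.0), 0.6, struct)
    obs[:, :, 1] = struct
    obs[:, :, 2] = np.where(tissue.mask, 0.5 * state.v, 0.0)
    if agent_pos is not None:
        r0, c0 = agent_pos
        obs[max(0, r0 - 1): r0 + 2, max(0, c0 - 1): c0 + 2, 2] = 1.0
    return obs


def initiate_rotor(
    tissue: TissueModel,
    scenario: rotors.RotorScenario,
    params: fk.FKParams,
    solver: fk.SolverConfig,
    settle_ms: float = 100.0,
    tip_tau_ms: float = rotors.TIP_TAU_MS,
) -> tuple[fk.EPState, np.ndarray]:
    """Cross-field initiation plus settling; returns (state, delayed u frame).

    The delayed frame trails the state by ``tip_tau_ms`` and feeds the
    phase-embedding tip detector at the first action.
    """
    state = fk.resting_state(tissue)
    state = rotors.apply_cross_field(state, tissue, params, solver, scenario)
    lead = max(settle_ms - tip_tau_ms, 0.0)
    state = fk.run(state, tissue, params, solver, lead)
    u_delayed = state.u.copy()
    state = fk.run(state, tissue, params, solver, tip_tau_ms)
    return state, u_delayed


class AblationEnv:
    """Conventional episodic environment: reset() / step(action) / render().

    The tissue passed in is never mutated; a working copy carries the
    lesions of the current episode.  In ``train`` mode the reward includes
    the rotor-tip and reference-lesion shaping terms; in ``eval`` mode both
    are disabled and the tip detector is never invoked (the counter
    ``shaping_evaluations`` stays 0).
    """

    n_actions = len(ACTIONS)

    def __init__(
        self,
        tissue: TissueModel,
        scenario: rotors.RotorScenario,
        params: fk.FKParams | None = None,
        solver: fk.SolverConfig | None = None,
        reward: RewardConfig | None = None,
        cfg: EnvConfig | None = None,
        mode: str = "train",
    ) -> None:
        if mode not in ("train", "eval"):
            raise ValueError(f"mode must be 'train' or 'eval', got {mode!r}")
        self.base_tissue = tissue
        self.scenario = scenario
        self.params = params or fk.default_params()
        self.solver = solver or fk.SolverConfig(dx=tissue.pixel_spacing)
        self.reward_cfg = reward or RewardConfig()
        self.cfg = cfg or EnvConfig()
        self.mode = mode
        self.shaping_evaluations = 0
        self._init_cache: tuple[fk.EPState, np.ndarray] | None = None
        self._done = True
        if self.cfg.ablation_interval_ms < self.cfg.tip_tau_ms:
            raise ValueError("ablation interval shorter than the tip-phase delay")

    # -- episode control ------------------------------------------------

    def reset(self, *, reuse_initiation: bool = True) -> np.ndarray:
        """Initiate the rotor and place the agent; returns the observation.

        Initiation is deterministic for a fixed tissue and scenario, so the
        post-initiation state is cached and reused by later resets of the
        same environment unless ``reuse_initiation`` is false.
        """
        if self._init_cache is None or not reuse_initiation:
            self._init_cache = initiate_rotor(
                self.base_tissue, self.scenario, self.params, self.solver,
                settle_ms=self.cfg.settle_ms, tip_tau_ms=self.cfg.tip_tau_ms,
            )
        state, u_delayed = self._init_cache
        self.tissue = self.base_tissue.copy()
        self.state = state.copy()
        self._u_delayed = u_delayed.copy()
        self._d_healthy = float(self.base_tissue.diffusion.max(initial=0.0)) or 1.0

        s = self.tissue.grid_size
        nom = rotors.nominal_point(self.scenario, s)
        off = self.cfg.agent_start_offset
        pos = (
            int(np.clip(nom[0] + round(off[0] * s), 0, s - 1)),
            int(np.clip(nom[1] + round(off[1] * s), 0, s - 1)),
        )
        healthy = self.tissue.healthy
        n_healthy = int(healthy.sum())
        if n_healthy == 0:
            raise ValueError("tissue has no healthy pixels")
        self.agent = AgentState(
            position=pos,
            ablated=np.zeros_like(self.tissue.mask),
            healthy_pixel_total=n_healthy,
        )
        self._healthy0 = healthy.copy()
        self.cumulative_reward = 0.0
        self.shaping_evaluations = 0
        self._done = False
        self._cause: str | None = None
        return self._observe()

    def step(self, action: int) -> tuple[np.ndarray, float, bool, dict]:
        """Ablate at the current position, move, simulate, reward, terminate."""
        if self._done:
            raise RuntimeError("episode is finished; call reset()")
        if not (isinstance(action, (int, np.integer)) and 0 <= int(action) < self.n_actions):
            raise ValueError(f"action must be an integer in 0..7, got {action!r}")
        action = int(action)
        prev = AgentState(
            position=self.agent.position,
            step_count=self.agent.step_count,
            direction_run=self.agent.direction_run,
            last_action=self.agent.last_action,
            ablated=self.agent.ablated,
            healthy_pixel_total=self.agent.healthy_pixel_total,
        )

        # 1. burn the lesion at the current position
        block = self._lesion_block(self.agent.position)
        overlapped = bool((block & self.agent.ablated).any())
        self.agent.ablated |= block
        self.tissue.diffusion[block] = 0.0

        # 2. move (blocked moves leave the agent in place but still count)
        dr, dc = ACTIONS[action]
        L = self.cfg.step_length
        cand = (self.agent.position[0] + dr * L, self.agent.position[1] + dc * L)
        s = self.tissue.grid_size
        if 0 <= cand[0] < s and 0 <= cand[1] < s and self.tissue.mask[cand]:
            self.agent.position = cand
        if action == self.agent.last_action:
            self.agent.direction_run += 1
        else:
            self.agent.direction_run = 1
        self.agent.last_action = action
        self.agent.step_count += 1

        # 3. rotor tips as the agent saw them (training shaping only)
        tips = None
        if self.mode == "train":
            tips = rotors.detect_rotor_tips(
                self.state.u, self._u_delayed, self.tissue.mask
            )
            self.shaping_evaluations += 1

        # 4. advance the simulation by the ablation interval
        interval = self.cfg.ablation_interval_ms
        tau = self.cfg.tip_tau_ms
        self.state = fk.run(self.state, self.tissue, self.params, self.solver,
                            interval - tau)
        self._u_delayed = self.state.u.copy()
        self.state = fk.run(self.state, self.tissue, self.params, self.solver, tau)

        # 5. outcome and termination
        success = rotors.is_quiescent(
            self.state, self.tissue, self.reward_cfg.quiescence_threshold
        )
        frac = healthy_ablated_fraction(self.agent, self._healthy0)
        over = (not success) and frac > self.reward_cfg.max_healthy_ablated_fraction
        limit = (not success and not over
                 and self.agent.step_count >= self.reward_cfg.max_steps)
        outcome = SimOutcome(
            success=success, over_ablation=over, step_limit=limit,
            new_lesion_overlapped=overlapped,
        )
        reward = compute_reward(
            prev, action, self.agent, outcome, tips,
            self.base_tissue.reference_lesions if self.mode == "train" else None,
            self.reward_cfg, self.mode,
        )
        self.cumulative_reward += reward
        self._done = success or over or limit
        if self._done:
            self._cause = ("success" if success
                           else "over_ablation" if over else "step_limit")
        info = {
            "tips": tips,
            "healthy_ablated_fraction": frac,
            "outcome": outcome,
            "terminal_cause": self._cause,
        }
        return self._observe(), reward, self._done, info

    def render(self) -> np.ndarray:
        """RGB uint8 frame: voltage red, rest blue, holes black, lesions yellow."""
        u = np.clip(self.state.u / 1.1, 0.0, 1.0)
        img = np.zeros((*u.shape, 3), dtype=np.uint8)
        m = self.tissue.mask
        img[..., 0] = np.where(m, 40 + 215 * u, 0).astype(np.uint8)
        img[..., 2] = np.where(m, 200 * (1.0 - u), 0).astype(np.uint8)
        img[self.agent.ablated] = (230, 220, 40)
        r0, c0 = self.agent.position
        img[max(0, r0 - 1): r0 + 2, max(0, c0 - 1): c0 + 2] = (40, 230, 40)
        return img

    # -- helpers --------------------------------------------------------

    def _lesion_block(self, pos: tuple[int, int]) -> np.ndarray:
        half = self.cfg.lesion_size // 2
        r0, c0 = pos
        s = self.tissue.grid_size
        block = np.zeros_like(self.tissue.mask)
        block[
            max(0, r0 - half): min(s, r0 + half + 1),
            max(0, c0 - half): min(s, c0 + half + 1),
        ] = True
        return block & self.tissue.mask

    def _observe(self) -> np.ndarray:
        return render_observation(
            self.state, self.tissue, self.agent.position, self._d_healthy
        )

    @property
    def done(self) -> bool:
        return self._done

    def result(self) -> EpisodeResult:
        """Summary of the finished episode."""
        if not self._done or self._cause is None:
            raise RuntimeError("episode is not finished")
        return EpisodeResult(
            success=self._cause == "success",
            steps=self.agent.step_count,
            ablated_points=self.agent.step_count,
            cumulative_reward=self.cumulative_reward,
            lesion_map=self.agent.ablated.copy(),
            terminal_cause=self._cause,
        )
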