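"""Scripted reference policies used by the environment and acceptance tests."""

from __future__ import annotations

import numpy as np

from ablateq import rotors
from ablateq.env import ACTIONS, AblationEnv


def toward_tip_action(env: AblationEnv, rng: np.random.Generator) -> int:
    """Move straight at the nearest detected rotor tip (random when none)."""
    tips = rotors.detect_rotor_tips(env.state.u, env._u_delayed, env.tissue.mask)
    if not tips:
        return int(rng.integers(0, 8))
    pos = np.array(env.agent.position, float)
    pts = np.array([(t[0], t[1]) for t in tips])
    tgt = pts[np.hypot(*(pts - pos).T).argmin()]
    moves = [np.hypot(*(pos + np.array(a) * env.cfg.step_length - tgt)) for a in ACTIONS]
    return int(np.argmin(moves))


class LatticePainter:
    """Boustrophedon coverage of a 9-px lesion lattice, avoiding a
    protected zone around the rotor site; used to drive an episode into
    the healthy-tissue over-ablation terminal."""

    def __init__(self, env: AblationEnv, exclusion_radius: float = 25.0) -> None:
        self.env = env
        s = env.tissue.grid_size
        nominal = rotors.nominal_point(env.scenario, s)
        self.waypoints: list[tuple[int, int]] = []
        for k, row in enumerate(range(6, s - 4, 9)):
            cols = list(range(6, s - 4, 9))
            if k % 2:
                cols.reverse()
            for col in cols:
                if env.tissue.mask[row, col] and \
                        np.hypot(row - nominal[0], col - nominal[1]) > exclusion_radius:
                    self.waypoints.append((row, col))
        self.stall = 0
        self._last_pos = None

    def __call__(self) -> int:
        env = self.env
        pos = np.array(env.agent.position)
        if self._last_pos is not None and tuple(pos) == self._last_pos:
            self.stall += 1
        else:
            self.stall = 0
        self._last_pos = tuple(pos)
        while self.waypoints and (
            np.hypot(*(pos - np.array(self.waypoints[0]))) < 3 or self.stall > 3
        ):
            self.waypoints.pop(0)
            self.stall = 0
        s = env.tissue.grid_size
        tgt = np.array(self.waypoints[0]) if self.waypoints else np.array([s // 2] * 2)
        best, best_d = 0, np.inf
        for i, a in enumerate(ACTIONS):
            cand = pos + np.array(a) * env.cfg.step_length
            if not (0 <= cand[0] < s and 0 <= cand[1] < s):
                continue
            if not env.tissue.mask[tuple(cand)]:
                continue
            d = np.hypot(*(cand - tgt))
            if d < best_d:
                best, best_d = i, d
        return best
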