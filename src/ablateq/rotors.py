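"""Rotor initiation, tracking and persistence on 2D atrial disks.

Rotors (re-entrant spiral waves) are started with a cross-field protocol: a
plane wave is launched from one edge of the tissue, and once its front has
traversed to a trigger line the voltage in a half-plane is reset to zero
(gates untouched).  The broken wave end curls into a rotor near the
scenario's nominal point.  Four canonical scenarios are provided: 1 and 2
are the training/testing pair (below the left superior PV; between the
inferior PVs, ~2.5 cm apart), 3 and 4 complete the recurrence-test set.

Rotor tips are phase singularities: points around which the activation
phase, reconstructed by time-delay embedding of the voltage, winds by
+/-2 pi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fenton_karma import (
    EPState,
    FKParams,
    SolverConfig,
    face_diffusivities,
    fk_step,
)
from .tissue import TissueModel

__all__ = [
    "RotorScenario",
    "SCENARIOS",
    "TIP_TAU_MS",
    "InitiationError",
    "InsufficientHistoryError",
    "nominal_point",
    "apply_cross_field",
    "detect_rotor_tips",
    "is_quiescent",
    "is_sustained",
]

#: Time-delay used for the phase embedding, ms.
TIP_TAU_MS = 10.0


class InitiationError(RuntimeError):
    """The plane wave never reached the trigger line (conduction blocked)."""


class InsufficientHistoryError(RuntimeError):
    """Tip detection needs a delayed voltage frame that is not yet available."""


@dataclass(frozen=True)
class RotorScenario:
    """One cross-field initiation recipe.

    ``stim_edge`` is the edge the plane wave starts from (N/S/E/W);
    ``nominal`` is the intended rotor-formation point as (row, col)
    fractions of the grid; the trigger line passes through the nominal
    point perpendicular to the propagation direction, and ``zero_side``
    says which side of the nominal point (along the front) is reset.
    """

    id: int
    stim_edge: str  # 'N', 'S', 'E', 'W'
    nominal: tuple[float, float]  # (row, col) as fractions of grid size
    zero_side: str  # 'lt' or 'gt' (indices below/above the nominal coordinate)

    def __post_init__(self) -> None:
        if self.stim_edge not in ("N", "S", "E", "W"):
            raise ValueError(f"bad stim_edge {self.stim_edge!r}")
        if self.zero_side not in ("lt", "gt"):
            raise ValueError(f"bad zero_side {self.zero_side!r}")


#: Canonical scenarios.  1: rotor just below the left superior PV
#: (wave from the bottom edge); 2: rotor between/below the inferior PVs
#: (wave from the top, left side zeroed, the classical picture);
#: 3 and 4: right-mid and left-lower sites for recurrence testing.
SCENARIOS: dict[int, RotorScenario] = {
    1: RotorScenario(1, "S", (44 / 150, 52 / 150), "gt"),
    2: RotorScenario(2, "N", (114 / 150, 88 / 150), "lt"),
    3: RotorScenario(3, "E", (70 / 150, 105 / 150), "lt"),
    4: RotorScenario(4, "W", (95 / 150, 48 / 150), "gt"),
}


def nominal_point(scenario: RotorScenario, grid_size: int) -> tuple[int, int]:
    """Nominal rotor-formation point in pixels for a given grid size."""
    return (
        int(round(scenario.nominal[0] * grid_size)),
        int(round(scenario.nominal[1] * grid_size)),
    )


def _stim_region(mask: np.ndarray, edge: str, depth: int) -> np.ndarray:
    region = np.zeros_like(mask)
    if edge == "N":
        region[:depth, :] = True
    elif edge == "S":
        region[-depth:, :] = True
    elif edge == "W":
        region[:, :depth] = True
    else:
        region[:, -depth:] = True
    return region & mask


def apply_cross_field(
    state: EPState,
    tissue: TissueModel,
    params: FKParams,
    cfg: SolverConfig,
    scenario: RotorScenario,
    timeout_ms: float = 600.0,
    stim_depth_frac: float = 0.04,
) -> EPState:
    """Run the two-stage cross-field protocol and return the broken-wave state.

    Stage 1 raises the voltage suprathreshold in a strip along the
    scenario's edge and integrates until the wavefront (u >= u_c) reaches
    the trigger line through the nominal point.  Stage 2 zeroes the voltage
    in the scenario's half-plane, leaving the gates untouched.  Raises
    :class:`InitiationError` if the front never arrives (e.g. conduction is
    blocked by lesions).
    """
    if not is_quiescent(state, tissue, threshold=1e-9):
        raise ValueError("cross-field initiation requires a resting tissue")
    s = tissue.mask.shape[0]
    row, col = nominal_point(scenario, s)
    depth = max(3, int(round(stim_depth_frac * s)))

    out = state.copy()
    stim = _stim_region(tissue.mask, scenario.stim_edge, depth)
    out.u[stim] = 1.0

    # The wave travels perpendicular to the stimulated edge; the trigger
    # line is the nominal row (vertical propagation) or column.
    vertical = scenario.stim_edge in ("N", "S")
    faces = face_diffusivities(tissue)
    cfg.check_stability(float(tissue.diffusion.max(initial=0.0)))
    n_max = int(round(timeout_ms / cfg.dt))
    arrived = False
    for _ in range(n_max):
        out = fk_step(out, tissue, params, cfg, faces=faces, _check=False)
        line_u = out.u[row, :] if vertical else out.u[:, col]
        line_m = tissue.mask[row, :] if vertical else tissue.mask[:, col]
        if line_m.any() and (line_u[line_m] >= params.u_c).any():
            arrived = True
            break
    if not arrived:
        raise InitiationError(
            f"scenario {scenario.id}: wavefront did not reach the trigger line "
            f"within {timeout_ms} ms"
        )

    # Stage 2: voltage reset of the half-plane on zero_side of the nominal
    # coordinate measured along the wavefront.
    if vertical:
        sl = (slice(None), slice(None, col)) if scenario.zero_side == "lt" else (
            slice(None), slice(col, None))
    else:
        sl = (slice(None, row), slice(None)) if scenario.zero_side == "lt" else (
            slice(row, None), slice(None))
    out.u[sl] = 0.0
    return out


def detect_rotor_tips(
    u_now: np.ndarray,
    u_delayed: np.ndarray,
    mask: np.ndarray,
    u_star: float = 0.3,
) -> list[tuple[float, float, int]]:
    """Locate phase singularities from two voltage frames tau apart.

    The activation phase is the time-delay embedding
    ``phi = atan2(u(t) - u*, u(t - tau) - u*)``; a rotor tip is an
    elementary 2x2 plaquette around which the wrapped phase difference sums
    to +/-2 pi.  Returns ``(row, col, charge)`` tuples at plaquette
    centres; an empty list for planar or quiescent activity.
    """
    if u_delayed is None:
        raise InsufficientHistoryError(
            "no delayed voltage frame yet: simulate at least the embedding "
            "delay before detecting tips"
        )
    if u_now.shape != u_delayed.shape:
        raise ValueError("voltage frames differ in shape")
    phi = np.arctan2(u_now - u_star, u_delayed - u_star)

    def wrap(d: np.ndarray) -> np.ndarray:
        return (d + np.pi) % (2.0 * np.pi) - np.pi

    # Circulation around plaquette (i,j)->(i,j+1)->(i+1,j+1)->(i+1,j)->(i,j)
    a = phi[:-1, :-1]
    b = phi[:-1, 1:]
    c = phi[1:, 1:]
    d = phi[1:, :-1]
    circ = wrap(b - a) + wrap(c - b) + wrap(d - c) + wrap(a - d)
    on_tissue = mask[:-1, :-1] & mask[:-1, 1:] & mask[1:, 1:] & mask[1:, :-1]
    hits = on_tissue & (np.abs(circ) > np.pi)  # circulation is 0 or +/-2pi
    rows, cols = np.nonzero(hits)
    return [
        (r + 0.5, cc + 0.5, int(np.sign(circ[r, cc])))
        for r, cc in zip(rows.tolist(), cols.tolist())
    ]


def is_quiescent(
    state: EPState, tissue: TissueModel, threshold: float = 0.2
) -> bool:
    """True iff u < threshold on every conductive, non-ablated pixel.

    Ablated pixels (mask true, diffusion 0) are excluded; an empty
    conductive set is quiescent by convention.
    """
    active = tissue.mask & (tissue.diffusion > 0)
    if not active.any():
        return True
    return bool(state.u[active].max() < threshold)


def is_sustained(
    state: EPState,
    tissue: TissueModel,
    params: FKParams,
    cfg: SolverConfig,
    horizon_ms: float = 2000.0,
    threshold: float = 0.2,
    tail_ms: float = 500.0,
    check_every_ms: float = 10.0,
) -> bool:
    """Does re-entrant activity persist to the end of the horizon?

    The state is advanced for ``horizon_ms``; activity counts as sustained
    iff quiescence never holds during the final ``tail_ms``.  Integration
    stops early once the voltage has decayed far below the excitation
    threshold everywhere, after which reactivation is impossible without a
    stimulus.
    """
    cfg.check_stability(float(tissue.diffusion.max(initial=0.0)))
    faces = face_diffusivities(tissue)
    out = state.copy()
    n_check = max(1, int(round(check_every_ms / cfg.dt)))
    n_total = int(round(horizon_ms / cfg.dt))
    tail_start = horizon_ms - tail_ms
    active = tissue.mask & (tissue.diffusion > 0)
    steps = 0
    while steps < n_total:
        for _ in range(min(n_check, n_total - steps)):
            out = fk_step(out, tissue, params, cfg, faces=faces, _check=False)
            steps += 1
        u_max = float(out.u[active].max()) if active.any() else 0.0
        if u_max < 0.01:  # fully sub-threshold: dead for good
            return False
        if out.t - state.t > tail_start and u_max < threshold:
            return False
    return True
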