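"""Fenton–Karma monodomain solver on 2D atrial tissue.

The three-current Fenton–Karma model describes the transmembrane variable
``u`` (dimensionless, 0 at rest, ~1 at the action-potential peak) together
with a fast gate ``v`` and a slow gate ``w``:

    du/dt = div(D grad u) - J_fi(u, v) - J_so(u) - J_si(u, w)
    J_fi  = -v * H(u - u_c) * (1 - u) * (u - u_c) / tau_d
    J_so  =  u * (1 - H(u - u_c)) / tau_0 + H(u - u_c) / tau_r
    J_si  = -w * [(1 + tanh(k * (u - u_c_si))) - (1 + tanh(-k * u_c_si))] / (2 * tau_si)
    dv/dt = (1 - H(u - u_c)) * (1 - v) / tau_v_minus(u) - H(u - u_c) * v / tau_v_plus
    dw/dt = (1 - H(u - u_c)) * (1 - w) / tau_w_minus   - H(u - u_c) * w / tau_w_plus

with H the Heaviside step and ``tau_v_minus(u)`` switching between two time
constants at the threshold ``u_v``.  Time is in milliseconds and space in
millimetres; the heterogeneous diffusion field ``D`` (mm^2/ms) comes from
the tissue model, zero off the conductive mask and in ablated lesions.

J_si carries a constant rest-anchoring offset (the bracketed subtraction,
~2e-8 for the default thresholds): without it the tanh tail leaves a tiny
residual inward current at u = 0, so the quiescent state would drift by
~1e-9/ms instead of being an exact fixed point.  The offset is far below
every dynamical scale of the model.

Integration is explicit (forward Euler) on a 5-point stencil with
arithmetic-mean face diffusivities.  No-flux boundaries — the outer disk
rim and every interior hole — are realised by dropping fluxes across faces
whose far side is non-conductive, which is equivalent to mirrored ghost
nodes for this stencil.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tissue import TissueModel

__all__ = [
    "FKParams",
    "EPState",
    "SolverConfig",
    "NumericalBlowUpError",
    "PARAM_SETS",
    "default_params",
    "resting_state",
    "face_diffusivities",
    "laplacian_term",
    "fk_step",
    "run",
    "measure_cv",
    "strip_tissue",
]


class NumericalBlowUpError(FloatingPointError):
    """The explicit integration produced a non-finite field value."""


@dataclass(frozen=True)
class FKParams:
    """Time constants (ms) and dimensionless thresholds of the ionic model."""

    tau_d: float
    tau_r: float
    tau_0: float
    tau_si: float
    tau_v_plus: float
    tau_v1_minus: float
    tau_v2_minus: float
    tau_w_plus: float
    tau_w_minus: float
    u_c: float
    u_v: float
    u_c_si: float
    k: float

    def __post_init__(self) -> None:
        for name in (
            "tau_d", "tau_r", "tau_0", "tau_si", "tau_v_plus",
            "tau_v1_minus", "tau_v2_minus", "tau_w_plus", "tau_w_minus",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("u_c", "u_v", "u_c_si"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


#: Named parameter sets.  "plateau" reproduces the classical long-plateau
#: dynamics (APD ~160 ms; wavelength too long for a 45 mm disk).  "af" is
#: the package default: a shortened-action-potential set in the style used
#: for fibrillating atria (APD ~71 ms, wavelength ~20 mm at the default
#: diffusivity), tuned so that a cross-field rotor is sustained on the
#: canonical 150-pixel disk while a single compartment of roughly half the
#: disk cannot sustain re-entry.  "af-short" is an even shorter variant
#: (APD ~45 ms) whose compact rotors survive in half-disk compartments.
PARAM_SETS: dict[str, FKParams] = {
    "plateau": FKParams(
        tau_d=0.25, tau_r=33.0, tau_0=12.5, tau_si=30.0,
        tau_v_plus=3.33, tau_v1_minus=1250.0, tau_v2_minus=19.6,
        tau_w_plus=870.0, tau_w_minus=41.0,
        u_c=0.13, u_v=0.04, u_c_si=0.85, k=10.0,
    ),
    "af": FKParams(
        tau_d=0.25, tau_r=35.0, tau_0=12.5, tau_si=35.0,
        tau_v_plus=3.33, tau_v1_minus=1250.0, tau_v2_minus=40.0,
        tau_w_plus=870.0, tau_w_minus=41.0,
        u_c=0.13, u_v=0.04, u_c_si=0.85, k=10.0,
    ),
    "af-short": FKParams(
        tau_d=0.25, tau_r=33.0, tau_0=12.5, tau_si=60.0,
        tau_v_plus=3.33, tau_v1_minus=1250.0, tau_v2_minus=19.6,
        tau_w_plus=870.0, tau_w_minus=41.0,
        u_c=0.13, u_v=0.04, u_c_si=0.85, k=10.0,
    ),
}


def default_params() -> FKParams:
    return PARAM_SETS["af"]


@dataclass
class EPState:
    """The dynamic fields at one time point (u, fast gate v, slow gate w)."""

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    t: float = 0.0

    def copy(self) -> "EPState":
        return EPState(self.u.copy(), self.v.copy(), self.w.copy(), self.t)


@dataclass(frozen=True)
class SolverConfig:
    """Discretisation: dt in ms (default 0.05), dx in mm (default 0.3)."""

    dt: float = 0.05
    dx: float = 0.3
    diffusion_only: bool = False  # drop reaction currents (validation mode)

    def __post_init__(self) -> None:
        if not (self.dt > 0 and self.dx > 0):
            raise ValueError("dt and dx must be positive")

    def check_stability(self, d_max: float) -> None:
        """Explicit-Euler diffusion stability: dt <= dx^2 / (4 D_max)."""
        if d_max > 0 and self.dt > self.dx**2 / (4.0 * d_max):
            raise ValueError(
                f"unstable discretisation: dt={self.dt} > dx^2/(4 Dmax)="
                f"{self.dx ** 2 / (4.0 * d_max):.4g}"
            )


def resting_state(tissue: TissueModel) -> EPState:
    """Quiescent fields: u = 0, both gates fully recovered (v = w = 1)."""
    shape = tissue.mask.shape
    return EPState(
        u=np.zeros(shape, dtype=np.float64),
        v=np.ones(shape, dtype=np.float64),
        w=np.ones(shape, dtype=np.float64),
        t=0.0,
    )


def face_diffusivities(tissue: TissueModel) -> tuple[np.ndarray, ...]:
    """Arithmetic-mean diffusivity on the N/S/W/E faces of every pixel.

    A face whose far side is off the conductive mask (outside the disk, in
    a PV/LAA hole) carries zero flux; this is the no-flux boundary.  Faces
    into ablated pixels (mask true, D = 0) keep the arithmetic mean, so a
    lesion at least two pixels wide is a full conduction block.
    """
    d, mask = tissue.diffusion, tissue.mask
    faces = []
    for shift in ((1, 0), (-1, 0), (0, 1), (0, -1)):  # N, S, W, E neighbour
        dn = np.zeros_like(d)
        ok = np.zeros_like(mask)
        src = (slice(None, -1), slice(None)) if shift == (1, 0) else \
              (slice(1, None), slice(None)) if shift == (-1, 0) else \
              (slice(None), slice(None, -1)) if shift == (0, 1) else \
              (slice(None), slice(1, None))
        dst = (slice(1, None), slice(None)) if shift == (1, 0) else \
              (slice(None, -1), slice(None)) if shift == (-1, 0) else \
              (slice(None), slice(1, None)) if shift == (0, 1) else \
              (slice(None), slice(None, -1))
        dn[dst] = d[src]
        ok[dst] = mask[src]
        faces.append(np.where(ok & mask, 0.5 * (d + dn), 0.0))
    return tuple(faces)


def _neighbour_shift(u: np.ndarray, which: int) -> np.ndarray:
    """Value of the N/S/W/E neighbour (0 where the neighbour is off-grid)."""
    un = np.zeros_like(u)
    if which == 0:  # north neighbour (row - 1)
        un[1:, :] = u[:-1, :]
    elif which == 1:  # south
        un[:-1, :] = u[1:, :]
    elif which == 2:  # west (col - 1)
        un[:, 1:] = u[:, :-1]
    else:  # east
        un[:, :-1] = u[:, 1:]
    return un


def laplacian_term(
    u: np.ndarray, tissue: TissueModel, cfg: SolverConfig,
    faces: tuple[np.ndarray, ...] | None = None,
) -> np.ndarray:
    """div(D grad u) on the conductive mask, zero-flux at every mask edge."""
    if faces is None:
        faces = face_diffusivities(tissue)
    fn, fs, fw, fe = faces
    flux = (
        fn * (_neighbour_shift(u, 0) - u)
        + fs * (_neighbour_shift(u, 1) - u)
        + fw * (_neighbour_shift(u, 2) - u)
        + fe * (_neighbour_shift(u, 3) - u)
    )
    return flux / (cfg.dx * cfg.dx)


def fk_step(
    state: EPState,
    tissue: TissueModel,
    params: FKParams,
    cfg: SolverConfig,
    faces: tuple[np.ndarray, ...] | None = None,
    _check: bool = True,
) -> EPState:
    """One forward-Euler update of (u, v, w); off-mask pixels are untouched."""
    if _check:
        cfg.check_stability(float(tissue.diffusion.max(initial=0.0)))
    u, v, w = state.u, state.v, state.w
    mask = tissue.mask

    with np.errstate(invalid="ignore", over="ignore"):
        return _fk_step_core(state, u, v, w, mask, tissue, params, cfg, faces, _check)


def _fk_step_core(state, u, v, w, mask, tissue, params, cfg, faces, _check):
    lap = laplacian_term(u, tissue, cfg, faces)
    if cfg.diffusion_only:
        du = lap
        u_new = u + cfg.dt * du
        v_new, w_new = v, w
    else:
        p = (u >= params.u_c).astype(np.float64)
        q = (u >= params.u_v).astype(np.float64)
        si_rest = 1.0 + np.tanh(-params.k * params.u_c_si)
        j_fi = -(v * p * (1.0 - u) * (u - params.u_c)) / params.tau_d
        j_so = u * (1.0 - p) / params.tau_0 + p / params.tau_r
        j_si = -(w * ((1.0 + np.tanh(params.k * (u - params.u_c_si))) - si_rest)) / (
            2.0 * params.tau_si
        )
        du = lap - (j_fi + j_so + j_si)
        u_new = u + cfg.dt * du

        tau_v_minus = q * params.tau_v1_minus + (1.0 - q) * params.tau_v2_minus
        dv = (1.0 - p) * (1.0 - v) / tau_v_minus - p * v / params.tau_v_plus
        dw = (1.0 - p) * (1.0 - w) / params.tau_w_minus - p * w / params.tau_w_plus
        v_new = np.clip(v + cfg.dt * dv, 0.0, 1.0)
        w_new = np.clip(w + cfg.dt * dw, 0.0, 1.0)

    u_new = np.where(mask, u_new, u)
    v_new = np.where(mask, v_new, v)
    w_new = np.where(mask, w_new, w)
    if _check and not np.isfinite(u_new).all():
        raise NumericalBlowUpError(
            f"non-finite voltage at t = {state.t + cfg.dt:.3f} ms "
            f"(step from t = {state.t:.3f} ms)"
        )
    return EPState(u_new, v_new, w_new, state.t + cfg.dt)


def run(
    state: EPState,
    tissue: TissueModel,
    params: FKParams,
    cfg: SolverConfig,
    duration: float,
) -> EPState:
    """Advance exactly round(duration / dt) explicit steps.

    Face diffusivities are computed once: the diffusion field must not
    change during the call (apply ablation between calls).
    """
    n_steps = int(round(duration / cfg.dt))
    if n_steps <= 0:
        return state.copy()
    cfg.check_stability(float(tissue.diffusion.max(initial=0.0)))
    faces = face_diffusivities(tissue)
    out = state
    for i in range(n_steps):
        out = fk_step(out, tissue, params, cfg, faces=faces, _check=False)
        if not np.isfinite(out.u).all():
            raise NumericalBlowUpError(
                f"non-finite voltage at step {i + 1} (t = {out.t:.3f} ms)"
            )
    return out


def strip_tissue(
    length_px: int = 120, width_px: int = 12, d: float = 0.05,
    pixel_spacing: float = 0.3,
) -> TissueModel:
    """Homogeneous rectangular strip used for conduction-velocity probes."""
    mask = np.zeros((width_px + 2, length_px + 2), dtype=bool)
    mask[1:-1, 1:-1] = True
    diff = np.where(mask, d, 0.0)
    return TissueModel(
        mask=mask, fibrosis=np.zeros_like(mask), diffusion=diff,
        pixel_spacing=pixel_spacing,
    )


def measure_cv(
    params: FKParams | None = None,
    cfg: SolverConfig | None = None,
    d: float = 0.05,
    length_px: int = 120,
    probe_frac: tuple[float, float] = (0.4, 0.75),
    max_time: float = 600.0,
) -> float:
    """Plane-wave conduction velocity (mm/ms) on a homogeneous strip.

    A stimulus at the left end launches a wave; the activation time (first
    up-crossing of u = 0.5) is recorded at two mid-row probes and the
    velocity is the probe separation over the time difference.  Raises if
    the wave never reaches the far probe (conduction failure).
    """
    params = params or default_params()
    cfg = cfg or SolverConfig()
    tissue = strip_tissue(length_px=length_px, d=d, pixel_spacing=cfg.dx)
    state = resting_state(tissue)
    state.u[:, 1:5][tissue.mask[:, 1:5]] = 1.0
    row = tissue.mask.shape[0] // 2
    c_a = 1 + int(probe_frac[0] * length_px)
    c_b = 1 + int(probe_frac[1] * length_px)
    t_a = t_b = None
    faces = face_diffusivities(tissue)
    cfg.check_stability(d)
    n_max = int(max_time / cfg.dt)
    for _ in range(n_max):
        state = fk_step(state, tissue, params, cfg, faces=faces, _check=False)
        if t_a is None and state.u[row, c_a] >= 0.5:
            t_a = state.t
        if state.u[row, c_b] >= 0.5:
            t_b = state.t
            break
    if t_a is None or t_b is None:
        raise RuntimeError(f"no propagating wave within {max_time} ms (D = {d})")
    return (c_b - c_a) * cfg.dx / (t_b - t_a)
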