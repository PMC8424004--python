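"""Independent reference implementations used only by the tests.

These deliberately re-derive behaviour in the most naive way possible
(scalar double loops, literal reward-table constants) so they share no
code path with the package implementation they check.
"""

from __future__ import annotations

import math

import numpy as np

from ablateq.fenton_karma import EPState


def fk_step_loop(state, tissue, params, cfg):
    """Unvectorised scalar forward-Euler step (reference for bit-equality).

    Mirrors the documented update rule operation by operation: face
    diffusivities are arithmetic means, fluxes across non-conductive faces
    are dropped, currents and gates follow the three-current model with
    the rest-anchored slow-inward term.
    """
    u, v, w = state.u, state.v, state.w
    mask, d = tissue.mask, tissue.diffusion
    h, wid = u.shape
    un = u.copy()
    vn = v.copy()
    wn = w.copy()
    si_rest = 1.0 + np.tanh(-params.k * params.u_c_si)
    for i in range(h):
        for j in range(wid):
            if not mask[i, j]:
                continue
            u0, v0, w0 = u[i, j], v[i, j], w[i, j]
            terms = []
            for ni, nj in ((i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)):
                if 0 <= ni < h and 0 <= nj < wid and mask[ni, nj]:
                    face = 0.5 * (d[i, j] + d[ni, nj])
                    terms.append(face * (u[ni, nj] - u0))
                else:
                    terms.append(np.float64(0.0) * (np.float64(0.0) - u0))
            flux = terms[0] + terms[1] + terms[2] + terms[3]
            lap = flux / (cfg.dx * cfg.dx)
            p = np.float64(1.0) if u0 >= params.u_c else np.float64(0.0)
            q = np.float64(1.0) if u0 >= params.u_v else np.float64(0.0)
            j_fi = -(v0 * p * (1.0 - u0) * (u0 - params.u_c)) / params.tau_d
            j_so = u0 * (1.0 - p) / params.tau_0 + p / params.tau_r
            j_si = -(w0 * ((1.0 + np.tanh(params.k * (u0 - params.u_c_si))) - si_rest)) / (
                2.0 * params.tau_si
            )
            du = lap - (j_fi + j_so + j_si)
            un[i, j] = u0 + cfg.dt * du
            tau_v_minus = q * params.tau_v1_minus + (1.0 - q) * params.tau_v2_minus
            dv = (1.0 - p) * (1.0 - v0) / tau_v_minus - p * v0 / params.tau_v_plus
            dw = (1.0 - p) * (1.0 - w0) / params.tau_w_minus - p * w0 / params.tau_w_plus
            vn[i, j] = np.clip(v0 + cfg.dt * dv, 0.0, 1.0)
            wn[i, j] = np.clip(w0 + cfg.dt * dw, 0.0, 1.0)
    return EPState(un, vn, wn, state.t + cfg.dt)


def reward_table_oracle(prev, action, nxt, outcome, tips, ref_lesions, mode):
    """Literal transcription of the published reward table (default
    constants only): every applicable row contributes independently."""
    total = 0.0
    terminal = False
    if outcome.success:  # all voltage below 0.2
        total += 420.0
        terminal = True
    if outcome.over_ablation:  # 40% of healthy tissue ablated
        total += -50.0
        terminal = True
    if outcome.step_limit:  # 80 steps taken
        total += -50.0
        terminal = True
    total += -1.0  # each step taken
    if outcome.new_lesion_overlapped:  # ablating already ablated tissue
        total += -5.0
    n = nxt.direction_run
    if n >= 2:  # consecutive moves in the same direction
        total += -(0.01 * math.exp(n))
    if mode == "train":
        if tips:
            d_prev = min(
                math.hypot(t[0] - prev.position[0], t[1] - prev.position[1]) for t in tips
            )
            d_next = min(
                math.hypot(t[0] - nxt.position[0], t[1] - nxt.position[1]) for t in tips
            )
            if d_next < d_prev:
                total += 15.0
            elif d_next > d_prev:
                total += -15.0
        if ref_lesions is not None and ref_lesions.any():
            pix = np.argwhere(ref_lesions)
            d_prev = min(
                math.hypot(r - prev.position[0], c - prev.position[1]) for r, c in pix
            )
            d_next = min(
                math.hypot(r - nxt.position[0], c - nxt.position[1]) for r, c in pix
            )
            if d_next < d_prev:
                total += 15.0
            elif d_next > d_prev:
                total += -15.0
    return total
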