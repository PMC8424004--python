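import numpy as np
import pytest

from ablateq import fenton_karma as fk
from ablateq import rotors
from ablateq.env import AblationEnv, EnvConfig
from ablateq.tissue import (
    SynthesisConfig,
    TissueModel,
    build_disk_geometry,
    build_diffusion_map,
    make_reference_lesions,
    synthesize_fibrosis,
)

DESK = dict(grid_size=75, pixel_spacing=0.6)
DESK_SOLVER = dict(dt=0.1, dx=0.6)


def make_tissue(grid_size=75, pixel_spacing=0.6, fibrosis_fraction=0.0,
                correlation_length=4.0, seed=0, reference_lesions=False) -> TissueModel:
    cfg = SynthesisConfig(
        grid_size=grid_size, pixel_spacing=pixel_spacing,
        fibrosis_fraction=fibrosis_fraction,
        correlation_length=correlation_length, seed=seed,
    )
    t = build_diffusion_map(synthesize_fibrosis(build_disk_geometry(cfg), cfg))
    if reference_lesions:
        t.reference_lesions = make_reference_lesions(t)
    return t


@pytest.fixture(scope="session")
def params():
    """Default ionic set used for the canonical full-scale physics."""
    return fk.default_params()


@pytest.fixture(scope="session")
def desk_params():
    """Compact-rotor AF substrate used by the desk training profile."""
    return fk.PARAM_SETS["af-short"]


@pytest.fixture(scope="session")
def desk_solver():
    return fk.SolverConfig(**DESK_SOLVER)


@pytest.fixture(scope="session")
def desk_tissue():
    """Homogeneous 75-pixel disk, 0.6 mm pixels (45 mm across)."""
    return make_tissue(**DESK)


@pytest.fixture(scope="session")
def desk_fibrotic_tissue():
    """Desk disk with 15% patchy fibrosis and PVI reference rings."""
    return make_tissue(**DESK, fibrosis_fraction=0.15, seed=3, reference_lesions=True)


@pytest.fixture(scope="session")
def canonical_tissue():
    """The full-scale 150-pixel homogeneous disk at 0.3 mm."""
    return make_tissue(grid_size=150, pixel_spacing=0.3)


@pytest.fixture(scope="session")
def canonical_rotor(canonical_tissue, params):
    """Scenario-1 cross-field initiation on the canonical disk.

    Returns the post-break state sampled for 200 ms (tip detections every
    10 ms) and whether activity persisted a further 2 s — shared by the
    rotor-machinery and recurrence checks because the simulation is
    deterministic.
    """
    solver = fk.SolverConfig()
    state = fk.resting_state(canonical_tissue)
    state = rotors.apply_cross_field(
        state, canonical_tissue, params, solver, rotors.SCENARIOS[1]
    )
    cur = state
    prev_u = state.u.copy()
    first_ps_ms = None
    first_tips = []
    for k in range(20):
        cur = fk.run(cur, canonical_tissue, params, solver, 10.0)
        tips = rotors.detect_rotor_tips(cur.u, prev_u, canonical_tissue.mask)
        prev_u = cur.u.copy()
        if tips and first_ps_ms is None:
            first_ps_ms = (k + 1) * 10.0
            first_tips = tips
    sustained_2s = rotors.is_sustained(
        cur, canonical_tissue, params, solver, horizon_ms=2000.0
    )
    return {
        "state_after_break": state,
        "state_200ms": cur,
        "first_ps_ms": first_ps_ms,
        "first_tips": first_tips,
        "sustained_2s": sustained_2s,
    }


@pytest.fixture(scope="session")
def desk_env_factory(desk_tissue, desk_fibrotic_tissue, desk_solver, desk_params):
    """Shared environments keyed by configuration; rotor initiation is
    cached inside each environment, so repeated resets are cheap."""
    cache: dict = {}

    def get(scenario_id=1, mode="train", fibrotic=False, **env_kw) -> AblationEnv:
        key = (scenario_id, mode, fibrotic, tuple(sorted(env_kw.items())))
        if key not in cache:
            cache[key] = AblationEnv(
                desk_fibrotic_tissue if fibrotic else desk_tissue,
                rotors.SCENARIOS[scenario_id],
                params=desk_params,
                solver=desk_solver,
                cfg=EnvConfig(**env_kw) if env_kw else None,
                mode=mode,
            )
        return cache[key]

    return get
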