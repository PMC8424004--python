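# ablateq

In-silico planning of catheter ablation for atrial fibrillation (AF) with
deep reinforcement learning.

Catheter ablation treats AF by burning small non-conductive lesions into
atrial tissue, but recurrence rates after standard lesion patterns remain
high. This package implements, end to end, an approach in which an agent
*learns* where to place lesions: a 2D left-atrial tissue model sustains a
re-entrant rotor (the driver of AF), and a deep Q-network is trained by
trial and error to move an ablation catheter across the tissue so that the
rotor is terminated with as little healthy tissue destroyed as possible.

It is aimed at computational cardiac-electrophysiology researchers who
want a self-contained, fully scriptable test bed: every component — tissue
synthesis, monodomain solver, rotor tracking, reward engine, agent,
experiment driver — is a plain Python module with no deep-learning
framework dependency.

## The model

**Tissue.** The left atrium is a standardised disk on a 150×150 grid
(0.3 mm/pixel), with four pulmonary-vein (PV) holes and an appendage hole.
Fibrosis is a patchy binary field synthesised from smoothed seeded noise
(or thresholded from an LGE-like intensity map via the image-intensity
ratio); it conducts slowly.

**Electrophysiology.** The monodomain equation with the three-current
Fenton–Karma ionic model:

    ∂u/∂t = ∇·(D∇u) − J_fi(u,v) − J_so(u) − J_si(u,w)

with fast gate `v`, slow gate `w`, diffusivity `D` = 0.05 mm²/unit-time in
healthy tissue and 0.0075 in fibrosis, forward-Euler integration at
dt = 0.05 ms, dx = 0.3 mm, and zero-flux boundaries at the disk rim and
every hole. Rotors are initiated with a cross-field protocol (plane wave,
then a half-plane voltage reset) and tracked as phase singularities of the
time-delay-embedded voltage.

**Episodes and reward.** At every step the agent ablates a 9×9-pixel block
(D := 0 permanently), moves one lesion-width in one of 8 compass
directions, and the simulation advances one ablation interval (10 ms
default). Reward components: +420 for termination (all voltage < 0.2),
−50 for ablating 40% of healthy tissue or reaching 80 steps (both
terminal), −1 per step, −5 for re-ablating, −0.01·e^N for N consecutive
same-direction moves, and ±15 training-only shaping terms for approaching/
retreating from the rotor tip and from reference lesion sets.

**Agent.** Twin convolutional Q-networks (2 × [conv 3×3 → maxpool 2×2 →
dropout 0.2] → dense → linear output over the 8 actions) with ε-greedy
exploration, uniform experience replay, MSE loss, Adam, and
target-network synchronisation every 5 episodes. The networks are
implemented in numpy with hand-written backpropagation.

## Worked example

A scripted "chase the rotor tip" policy on a reduced 75×75 desk tissue
(same 45 mm disk at 0.6 mm/pixel):

```python
import numpy as np
from ablateq.tissue import (SynthesisConfig, build_disk_geometry, synthesize_fibrosis,
                            build_diffusion_map, make_reference_lesions)
from ablateq import fenton_karma as fk, rotors
from ablateq.env import AblationEnv, ACTIONS

cfg = SynthesisConfig(grid_size=75, pixel_spacing=0.6,
                      fibrosis_fraction=0.15, correlation_length=4.0, seed=7)
tissue = build_diffusion_map(synthesize_fibrosis(build_disk_geometry(cfg), cfg))
tissue.reference_lesions = make_reference_lesions(tissue)
print(f"tissue: {tissue.grid_size}x{tissue.grid_size} px, "
      f"fibrosis {tissue.fibrosis.sum() / tissue.mask.sum():.1%} of the disk")

env = AblationEnv(tissue, rotors.SCENARIOS[1],
                  params=fk.PARAM_SETS["af-short"],
                  solver=fk.SolverConfig(dt=0.1, dx=0.6))
obs = env.reset()
print(f"observation {obs.shape}, rotor initiated near "
      f"{rotors.nominal_point(env.scenario, 75)}")

rng = np.random.default_rng(0)
while not env.done:
    tips = rotors.detect_rotor_tips(env.state.u, env._u_delayed, env.tissue.mask)
    if tips:  # chase the nearest phase singularity
        pos = np.array(env.agent.position, float)
        pts = np.array([(t[0], t[1]) for t in tips])
        tgt = pts[np.hypot(*(pts - pos).T).argmin()]
        action = int(np.argmin([np.hypot(*(pos + np.array(a) * 9 - tgt))
                                for a in ACTIONS]))
    else:
        action = int(rng.integers(8))
    obs, reward, done, info = env.step(action)

res = env.result()
print(f"episode: {res.terminal_cause} after {res.steps} steps, "
      f"{res.ablated_points} lesions, cumulative reward {res.cumulative_reward:.1f}")
```

prints

```
tissue: 75x75 px, fibrosis 15.0% of the disk
observation (75, 75, 3), rotor initiated near (22, 26)
episode: success after 23 steps, 23 lesions, cumulative reward 541.4
```

The agent followed the meandering phase singularity, ablated through its
core, and the episode ended in the success terminal (+420, plus the
accumulated shaping rewards, minus the step costs) when the whole disk
dropped below the 0.2 voltage threshold.

Training and evaluation run through the driver:

```python
from ablateq.orchestrate import desk_profile, train_agent, evaluate_agent
result = train_agent(desk_profile(seed=0, episodes=120))
print(result.blocks)         # per-50-episode success rates, lesion counts
```

or from the shell: `ablateq make-tissues ...`, `ablateq train ...`,
`ablateq evaluate ...`, `ablateq recurrence ...`, `ablateq render ...`.

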