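# Methods

## Tissue model

The left atrium is represented as a standardised 2D disk: a 150×150 pixel
grid at 0.3 mm/pixel (45 mm across), conductive inside the disk except for
four pulmonary-vein holes (radius 1.4 mm, on a ring at 0.32 of the grid
from the centre: two superior, two inferior) and one appendage hole at
mid-left (radius 1.8 mm). All positions are grid-fraction constants, so
the same layout is produced at any resolution. Holes and the outer rim are
non-conductive; the appendage is treated exactly like a PV hole because
the solver distinguishes only tissue from not-tissue.

Fibrosis is synthesised as Gaussian-smoothed seeded white noise
thresholded at the empirical quantile that yields a target area fraction
(default 25% of the disk, correlation length 6 pixels at full scale). This
emulates the patchy, spatially correlated appearance of late-gadolinium
enhancement; it does **not** emulate real atrial anatomy, wall-thickness
or fibre anisotropy, transmural heterogeneity, or the geometric
distortions of unwrapping a 3D atrium onto a disk. Passing tests therefore
demonstrate correctness of the pipeline on a controlled substrate, not
clinical validity. Real LGE-like images can be imported instead: a pixel
is fibrotic when its intensity divided by the blood-pool mean exceeds a
user-chosen image-intensity-ratio threshold (no default is supplied — the
appropriate value depends on the acquisition).

Reference lesion sets (used only by a training-time shaping reward) are
rings encircling each PV hole — a pulmonary-vein-isolation surrogate.

## Electrophysiology

The monodomain equation with the three-current Fenton–Karma ionic model is
integrated by forward Euler on a 5-point stencil. Face diffusivities are
arithmetic means of the two adjacent pixels; fluxes across faces whose far
side is non-conductive are dropped, which equals mirrored ghost nodes and
gives zero-flux boundaries at the rim and all holes uniformly. The
stability bound dt ≤ dx²/(4·D_max) is enforced. A lesion (D = 0, mask
still true) at least two pixels wide is a full conduction block; its
one-pixel boundary layer can still be passively depolarised, which is why
quiescence is evaluated on conductive *non-ablated* pixels only.

Diffusivities are 0.05 (healthy) and 0.0075 (fibrotic) mm² per unit time,
with the unit read as milliseconds so that conduction velocity is
physiological (≈0.3 mm/ms in healthy tissue); the healthy:fibrotic ratio
is exactly 0.05/0.0075. Two named ionic parameter sets ship; both are the
classical 13-parameter formulation with modified repolarisation time
constants, and the slow-inward current carries a constant rest-anchoring
offset (≈2×10⁻⁸) so that u = 0, v = w = 1 is an exact fixed point:

| set | APD | CV | wavelength | role |
|---|---|---|---|---|
| `af` (default) | ≈71 ms | ≈0.29 mm/ms | ≈20 mm | canonical-disk physics and recurrence benchmarks: the rotor is sustained on the 45 mm disk, but a compartment of half the disk cannot sustain re-entry |
| `af-short` | ≈45 ms | ≈0.29 mm/ms | ≈13 mm | episode substrate for training/testing: compact, robust rotors that persist for the whole episode horizon |

The wavelength cannot serve both purposes at once: a rotor that fits
comfortably in a half-disk (short wavelength) survives any single lesion
line, while a rotor near the disk-size limit (long wavelength) is
marginal — parameter sets with APD ≥ 76 ms break up and self-terminate
within ~0.7 s on the full disk. The `af` set sits on the boundary between
the two regimes; it was calibrated by forward simulation (APD/CV
measurement, 2 s persistence on the canonical disk, compartment-death
checks) and then frozen.

## Rotor initiation, scenarios, tracking

Rotors are initiated by a cross-field protocol: a plane wave from one edge
propagates to a trigger line through the scenario's nominal point, then
the voltage in a half-plane is reset to zero (gates untouched); the broken
end curls into a rotor near the nominal point. Four canonical scenarios
are defined by grid-fraction constants: 1 below the left superior PV
(wave from the bottom edge), 2 between/below the inferior PVs (wave from
the top, left side zeroed), separated by ≈24 mm, and 3–4 at right-mid and
left-lower sites completing the recurrence set. Sites 3–4 were selected
among sector candidates by measured pre-ablation rotor lifetime on the
canonical disk (most stable wins; ties keep the first candidate).

Rotor tips are phase singularities of the time-delay embedding
φ = atan2(u(t) − u*, u(t − τ) − u*) with τ = 10 ms and u* = 0.3: a tip is
an elementary 2×2 plaquette whose wrapped phase circulation is ±2π. On an
analytic Archimedean spiral the detector localises the singularity within
one pixel.

`is_sustained` advances the state over a horizon (default 2 s) and
declares re-entry sustained iff quiescence (max u < 0.2 on conductive
non-ablated tissue) never holds during the final 500 ms; integration
stops early once the voltage is everywhere below 0.01, after which
reactivation is impossible without a stimulus.

## Episodes and rewards

Each step: ablate a 9×9 block at the agent position, move one lesion
width (9 px) in one of 8 compass directions (blocked moves leave the agent
in place but still count), advance the simulation by the ablation interval
(10 ms default, 50 ms variant), then score. The reward is the exact sum of
the published components (+420 success; −50 over-ablation at >40% of
healthy tissue; −50 at the 80-step cap; −1 per step, also on terminal
steps; −5 for overlapping previous lesions; −0.01·e^N from the second
consecutive same-direction move, implemented negative although the table
prints the magnitude; ±15 rotor-tip and reference-lesion proximity terms,
training mode only, suppressed when no tip is detectable or the distance
is unchanged, nearest tip when several coexist). The environment exposes
the conventional reset/step/render API; observations are 3-channel images
with fixed normalisation (u/1.1; a structure channel with distinct
healthy/fibrotic/ablated/outside levels; the v gate at half intensity plus
a bright 3×3 agent marker).

## Agent

Twin CNNs (per block: 3×3 convolution with ReLU → 2×2 max-pool → dropout
0.2; two blocks; flatten; hidden dense layer; linear 8-way output), MSE
loss on the taken action's output only, Adam, uniform replay, ε-greedy
with per-episode exponential decay, target network synchronised every 5
episodes, best-checkpoint-per-50-episodes retention on strict improvement.
Layers and backpropagation are implemented directly in numpy (verified
against finite differences); max-pool routes gradient to the argmax
element only, because with ReLU inputs all-zero windows tie on every
element and duplicating the gradient four-fold destabilises training.

Three numerical safeguards keep float32 learning stable: rewards entering
the replay buffer are scaled by 1/42 and clipped to [−2, +11] in scaled
units (the clip binds only beyond ±84 raw points, i.e. on the unbounded
e^N direction penalty, and never touches the +420 success term), and
minibatch gradients are rescaled to a global norm of 10 when they exceed
it. The direction-run count N is not part of the observation, so the
same state–action pair can score −1 or −10⁴ depending on unobserved
history; without the clip this non-Markov variance makes value estimates
of any repeated action diverge.

Defaults: γ = 0.95, ε from 1.0 to 0.05 with decay 0.99413 (≈0.1 by
episode 500), batch 64, replay 20 000, learning rate 10⁻³, one learn step
per environment step. All are configurable.

## Reduced-scale profile

`desk_profile()` runs the full loop on one CPU: the same 45 mm disk on a
75×75 grid (0.6 mm/pixel, dt = 0.1 ms — far inside the stability bound),
fibrosis 15% at 4-pixel correlation (at 0.6 mm the slow fibrotic
conduction is near the discrete propagation limit, so the full-scale 25%
burden would block initiation outright — a resolution artifact), `af-short`
ionic set, 12 training tissues, 120 episodes, 8-filter conv blocks,
dense 32, batch 32, γ = 0.8, learn step every second environment step,
ε floor 0.1 with decay 0.95.

Two properties of this profile matter for interpreting results:

1. **Episode mechanics are full-fidelity.** Reward arithmetic, termination
   rules, rotor machinery and the recurrence check behave identically to
   full scale and are what the test suite verifies.
2. **The learning comparison is scale-limited.** The step budget (80),
   lesion size (9×9) and 40% ablation cap are full-scale constants; on a
   quarter-area arena 80 lesions cover most of the disk, so a uniformly
   random policy already terminates the rotor by attrition in roughly
   three quarters of episodes — close to the ceiling of any policy. At the
   same time, 120 episodes provide on the order of 10³ gradient steps,
   far below what learning the image-to-action mapping needs. The
   trained-vs-random comparison at this scale therefore measures the
   attrition ceiling more than policy quality, and the acceptance suite's
   desk-scale "trained beats random" check fails honestly under these
   conditions. The full-scale configuration (whose 900-episode training
   loop needs weeks of single-CPU compute) is expressed by the default
   `RunConfig` but is not exercised by the tests.

## Design choices on open points

- 8 compass moves of one lesion width, ablate-then-move ordering.
- The −1 step cost is charged on terminal steps as well (flag available).
- Blocked moves: agent stays put, step still costs −1.
- Tip shaping uses the nearest singularity of possibly many; both ±15
  terms are suppressed for steps with no detectable tip.
- Agent start: a fixed offset of (0.12, 0.12) grid fractions from the
  scenario's nominal point.
- Direction penalty sign: negative (the table prints the magnitude).
- Train/test tissue pools are generated from disjoint seed streams.
- A tissue whose rotor dies during the settling interval is re-initialised
  once, then skipped and logged; skipped episodes are excluded from
  success-rate denominators.

## Known limitations

- 2D monodomain with isotropic diffusion; no anisotropy, no 3D, no
  restitution tuning against patient data.
- The synthetic substrate lacks anatomical realism (see Tissue model);
  conclusions transfer to the method, not to patients.
- Whether a single straight lesion line compartmentalises the disk depends
  on the ionic set and scenario geometry; the recurrence benchmark uses
  the horizontal diameter with the default `af` set, for which all four
  re-initiation scenarios are prevented.
- Desk-scale learning is informative only as a plumbing check (see above).
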