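# Methods

This note documents the model the package implements, the choices that
were genuinely open, and what the simulations do and do not capture.

## The model

Each sperm is a point agent on a 2D plane with a heading, advanced in
60 ms frames for 30 simulated minutes (30,000 frames). Per frame the
engine (1) reads the chemoattractant concentration at the sperm position,
(2) binds receptors, (3) ages/expires binding cohorts (sea urchin),
(4) draws the frame's cGMP production, (5) fires a turn if cGMP reaches
threshold — removing the bound pool at that instant in the starfish —
(6) advances the kinematics one exact circular arc, and (7) tests arrival
(distance to egg center ≤ 100 μm, absorbing).

### Chemoattractant field

The field is the time-independent solution of the radial diffusion
(Laplace) equation with the concentration pinned to 100 pM at the egg
surface (radius 100 μm, egg coat included) and zero at the field edge.
The geometry is fixed at field **radius** 5000 μm: with the logarithmic
closed form this reproduces the reference concentrations 59 pM at 500 μm,
9 pM at 3500 μm and 257 fM at 4950 μm, which a 2500 μm radius does not.
Diffusion constants and ligand decay drop out of the steady-state
equation and are not modeled. Concentrations are held in nM internally
(K½ is quoted in nM); pM/fM appear only at interfaces. Positions beyond
the edge see zero concentration; positions inside the egg clamp to the
surface value.

### Receptor signaling

Binding follows the negatively cooperative Hill curve (K½ = 0.65 nM,
h = 0.49). Because GC–ligand binding takes ~2 min to equilibrate, only
1/2000 of the equilibrium occupancy binds per frame:
`new = active · Hill(C) / 2000`, rounded stochastically (floor plus a
Bernoulli trial on the fractional part) so that sub-unit expected
bindings in the far field are not systematically lost; `floor` and
`round` modes are available. Each bound receptor produces 4.3 ± 1.7 cGMP
per frame. The default draw granularity is **one normal draw per sperm
per frame** multiplied by the bound count (`draw_mode: per_frame`),
clamped at zero; a central-limit `per_receptor` variant (SD scaling with
√B) is provided. The per-frame variant keeps the larger per-frame
variance, which supplies the stochasticity of turning; both variants were
exercised during development and the cohort-level contrasts below hold
under either. cGMP lives a single frame; the turn fires when the frame's
total is ≥ 100 (threshold comparison inclusive — immaterial in practice
since the signal is real-valued).

Desensitization: a sea urchin binding cohort produces for three full
frames and is then moved to a permanently desensitized pool (160 ms
lifetime at 60 ms frames; whether the biological window is frames 0–2 or
1–3 is unknowable from the published description — cohorts here get three
production frames). The starfish bound pool persists and produces until a
turn fires, at which moment it is removed in one step. No resensitization
occurs on the 30 min horizon. Receptor conservation
(active + bound + desensitized = initial) is enforced and tested at every
frame.

**Frozen control.** The frozen ("desensitization off") condition skips
the removal step entirely, for both species: bound receptors stay bound
and keep producing. The signal then saturates far above threshold and the
sperm turns at every opportunity, in a deterministic,
concentration-insensitive cycle — it loses chemotaxis not by losing the
signal but by losing the *modulation* of the signal. An alternative
frozen semantics (returning removed receptors to the active pool) was
implemented first and rejected: it preserves the concentration dependence
of the turn cycle through pool resetting, and the frozen starfish then
still reached the egg from 400–1000 μm at 10–50% rates — the opposite of
the phenotype the control is meant to demonstrate.

### Motility

Baseline kinematics (not printed in the modeling description; taken from
the trajectory literature the models are built on): speed 150 μm/s,
circling radius 25 μm (κ₀ = 0.04 μm⁻¹), clockwise. A turn scales the
baseline curvature by a fixed per-frame multiplier sequence — a
high-curvature loop, a sub-baseline run, and a ramp back to 1.0 —
followed by a refractory period during which triggers are ignored.
Integration is by exact arcs (rotate the heading by θ = vκ·dt, translate
along the chord), so the closed baseline circle and arrival statistics
carry no integrator error; equivalence with heavily oversampled Euler
integration is tested to < 0.01 μm/frame.

**Turn-profile calibration.** The published curvature profiles exist only
as figures, so the coefficients here are package data, calibrated once at
the trajectory level and then frozen. Two quantities organize the
behavior: the episode's net displacement of the circling center `D`
(step size of the resulting walk) and the net rotation of a full
saturated turn cycle (profile + refractory), taken modulo 360°. A
turn-saturated sperm repeats an identical cycle, so its path is a bounded
orbit of radius ≈ |D| / (2·sin(rot/2)); cycle rotations near 0° make the
saturated walker quasi-ballistic, large ones lock it in place. The
calibrated sea urchin profile (15 frames, peak 2.5×, dip 0.4×, refractory
5 frames; cycle rotation ≈ −24° mod 360) keeps the early saturated phase
mobile; the starfish profile (9 frames, peak 2.45×, dip 0.35×, refractory
3 frames; ≈ +42° mod 360) is shorter — its smaller accumulation window
keeps the discrete scheme responsive farther down the gradient — and its
larger cycle rotation bounds the frozen orbit, which is what makes the
frozen starfish fail beyond 300 μm while still reaching from 200 μm.
Chemoattractant is sampled at the head position once per frame; the
flagellum is not resolved.

### Engine

Start pose: the agent is placed exactly at (start distance, 0) with its
circling center at a uniform-random bearing and the heading tangential; a
`fixed_phase` switch removes the phase randomization. Agents that leave
the field keep swimming in zero concentration (no wall, no reflection)
and may wander back — though a starfish that spends its bound pool
outside never turns again, so the edge is effectively absorbing for it.
The egg-oscillation disturbance moves the egg center along
(0, A·sin 2πft)), evaluated once per frame for both the field lookup and
the arrival test; frequencies above the 8.33 Hz frame Nyquist alias, as
they must at this time resolution (10² Hz, a multiple of the frame rate,
aliases to a static egg).

All randomness is a counter-based RNG: a vectorized splitmix64 hash of
(master seed, agent index, frame, draw slot), uniforms mapped to normals
through the inverse CDF. numpy's generator API cannot vectorize over
per-agent keys, so this small primitive is implemented here; it makes
every agent's stream a pure function of (seed, index) — cohorts are
bit-reproducible, independent of execution order or batching, and the
single-agent runner replays any cohort member exactly (tested against a
scalar reference implementation of the whole loop, frame by frame).

## Parameters

| parameter | default | units | note |
|---|---|---|---|
| K½ | 0.65 | nM | half-saturation of GC–ligand binding |
| h | 0.49 | – | Hill coefficient (negative cooperativity) |
| binding divisor | 2000 | – | slow-binding kinetic factor per frame |
| cGMP rate | 4.3 ± 1.7 | molecules/frame | per bound GC, clamped ≥ 0 |
| cGMP threshold | 100 | molecules | per-frame total that fires a turn |
| initial GC | 300,000 / 110,000 | – | sea urchin / starfish |
| cohort lifetime | 3 | frames | sea urchin continuous scheme |
| egg radius | 100 | μm | arrival radius, includes egg coat |
| field radius | 5000 | μm | zero-concentration boundary |
| surface concentration | 100 | pM | at the egg surface |
| speed | 150 | μm/s | fixed |
| circling radius | 25 | μm | clockwise |
| refractory | 5 / 3 | frames | sea urchin / starfish |
| duration | 30,000 | frames | 30 min |
| n per cohort | 10,000 | – | headline experiments |

The quoted uncertainties on K½ (±0.08) and h (±0.03) are receptor
constants, not per-event noise: they are scan ranges for the robustness
experiments, never sampled per frame.

## What the simulations emulate — and not

The simulator *is* the data generator: there is no external data. It
emulates 2D planar swimming in a quiescent, unbounded-depth fluid with a
static (or rigidly oscillating) egg, one sperm at a time. It does not
emulate 3D helical swimming, hydrodynamic interactions or walls,
continuous Ca²⁺-coupled curvature modulation, the cGMP→CNGK→pH→Ca²⁺
cascade below the threshold abstraction, receptor resensitization, or
variability between cells. Passing tests therefore show that the
*algorithmic* claims hold — desensitization-dependent long-range
chemotaxis, the species contrast, disturbance tolerance — not that the
parameter values transfer quantitatively to sea water.

## Test and experiment sizes

The test suite runs cohorts of n = 2,000 (n = 10,000 for the long-range
reach check) at the full 30-minute horizon, a size chosen to resolve the
tested contrasts well beyond their binomial error; the acceptance script
uses n = 10,000 throughout, matching the headline experiments.

## Known limitations

* Turn-profile coefficients are calibrated approximations; absolute
  arrival rates inherit that uncertainty (the 2000 μm sea urchin rate is
  reproduced at ~2% against a reported ~1.5%), and the sea urchin/starfish
  crossover sits near 1500–1800 μm rather than ~1300 μm.
* Long-range starfish reach: with the calibrated geometry no sperm
  reaches the egg from 4.6 mm in 10,000 trials. The frozen-control
  constraint (no arrivals beyond 300 μm) bounds the saturated-phase orbit
  and with it the transport available before receptors deplete; within
  this reconstruction the two phenotypes trade off, and the package keeps
  the frozen contrast — the mechanism the models exist to demonstrate —
  at the cost of the extreme-range tail. The corresponding acceptance
  check is left failing rather than loosened.
* The frozen-mode semantics (skip the subtraction, pool stays bound) is
  an interpretation; see the design discussion above for why the
  alternative was rejected.
* Cell-to-cell parameter variability is not modeled; every agent in a
  cohort shares identical parameters and differs only in its random
  stream.
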