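# Methods

This note documents the models implemented in `platesim`, the choices made
where the design was genuinely open, and what the packaged parameter set
does and does not claim.

## Conventions

Positions are Cartesian micrometres, origin at the bottom-left plate
corner, y up; cells are points carrying scalar volume (µm³) and projected
surface (µm²). Time is minutes. The default update interval is 20 min;
because every stochastic edge stores its probability together with a
reference time and is adapted per interval (memoryless hazard,
`p(Δt) = 1 − (1−p)^{Δt/T}`), any interval from a few minutes to a few
hours yields consistent dynamics. Scalar fields are static lattices
(default node spacing 10 µm) sampled by bilinear interpolation; there is
no diffusion — fields only decay (half-life) and are consumed around
cells.

Reproducibility: one master seed per run; every cell draws from an
independent RNG substream keyed by its id, and events use a dedicated
stream, so results are bit-identical for a fixed seed and independent of
iteration order. Within an interval all cells read the previous
interval's neighbour grid and fields (synchronous update).

## Cell cycle

Phases: G1, G1c (committed late G1), S, G2, M, G0, APO, DAMAGED, DEAD.
At most one transition is drawn per cell per interval; with Δt ≤ 60 min
and the packaged rates this loses well under 1% of double-jump mass.
Edges between the same phase pair may appear more than once: parallel
edges give OR semantics between independent causes (e.g. quiescence entry
by starvation *or* by crowding), which a single multiplicatively-combined
factor list cannot express. Factor effects multiply the base probability;
an effect's direction (enhancing/limiting) is encoded by the sign given
to the logistic steepness.

Hard gates override the draws: S entry requires the replication-licensing
flag (set on entering G1c), G2 entry requires `dna_fraction == 1`. DNA
advances deterministically at `1/s_phase_minutes` per minute in S
(packaged: 360 min).

Growth is exponential per phase with a per-cell log-normal modifier
(σ = 0.1, drawn at birth) producing the between-cell growth variability
seen in single-cell volume traces. Crucially, **G0 cells keep growing at
the G1 rate** (scaled by serum and confluence logistic factors): the
replication clock is volumetric doubling, so transient quiescence does
not distort the realized replication time, while starved or confluent
cells grow negligibly because the serum/confluence growth factors are
near zero there. Division splits the volume 50/50 with a ±5% Gaussian
asymmetry; daughters restart in G1/SPREADING with fresh growth modifiers.

The mean age at mitosis over a finite run slightly underestimates the
volumetric doubling time (stochastic gate lags; divisions not yet
observed for slow cells at the end of the window). The packaged growth
rate carries a single calibration factor (1.095 on the nominal cycle) so
that a standard 3-day, 100-cell experiment reports a mean replication
time matching the nominal 24 h.

### Packaged NIH3T3-like parameter set

The cell-type library values are *not* measured molecular rates; they
were calibrated by simulation against population-level reference
behaviour: ~24 h mean age at mitosis; an exponential 10%-serum day-3
state with ≥50% G1 and ~20% G0; ~52% G0 at 2.5% serum; ≥79% G0 after a
0.5% FBS step-down; a confluent stationary state with ~70–80% G0 whose
cell count is independent of seeding density. The main levers: a volume
gate on G1→G1c (x_ref 1500 µm³) sets G1 length; serum logistic factors
on commitment and on the two quiescence arms set the serum response; a
crowding arm on G0 entry plus confluence limits on commitment and growth
produce contact inhibition and the stationary plateau.

Apoptosis uses small baseline rates raised by starvation and crowding
("a small portion" of spontaneous death under standard conditions);
apoptotic cells drain vitality (≈3 h to death). Damaged cells recover or
die with logistic probabilities of the damage level around a half-point
of 0.5. Drugs drain vitality per molecule concentration unless a
protective gene is present. Reporter kinetics are linear
synthesis/decay with phase-dependent rates chosen so the quiescent
steady state of p27 is ~25× the cycling one; absolute units are
arbitrary.

## Attachment

DETACHED → ATTACHED → SPREADING → SPREAD with stochastic first edges and
deterministic spreading ramps (120 min to full spread, 30 min to
de-spread); entering M or APO forces DESPREADING, and daughters restart
from the mitotic minimum (spread fraction 0.1). The projected footprint
is `c·V^{2/3}·(1 + (s_max−1)·spread_fraction)` with c = 1.21 (spherical
cross-section) and s_max = 4 — an invented closed form reproducing the
qualitative shape of surface-vs-age data (steep early rise from
spreading, then volume tracking, dips at mitosis). Detached cells grow
at 20% of the attached rate and move at 5% (motility multiplier).

## Motion

The displacement generator is the three-component model. The random
vector is the resultant of ten equal-length steps with i.i.d. uniform
directions; the step length is `module / 2.820439`, where 2.820439 is the
mean resultant length of the ten-step unit walk (computed once by
high-precision Monte Carlo), so the *mean* random displacement equals the
requested module. The persistence vector lies along the previous *actual*
(post-constraint) displacement; the first step of a path has none. The
bias vector sums the cell type's global bias with per-cell extra biases:

* **repulsion** — for each neighbour within `repulsion_radius` (40 µm), a
  vector away from it with module `sensitivity·d_ref·(1 − dist/radius)`
  (linear falloff; a pluggable kernel). Coincident cells push in a
  uniformly random direction (tie-break).
* **gradients** — the field sampled half a sensing distance (10 µm)
  ahead/behind along each axis; bias = gain × finite difference, capped
  at d_tot so sharp fields cannot teleport a cell in one step.

Conditions enter through `d_tot = k·d_ref` with k the product of
per-phase (G0 0.4, M 0.3, APO 0.2) and per-attachment multipliers,
vitality, a confluence logistic, and Δt relative to the 20-min reference
interval. The combined bias defines b' = |bias|/d_tot; r and p are
rescaled so r' + p' + b' = 1 (bias capped at d_tot when b' ≥ 1).
Constraints truncate displacements stop-at-wall (no reflection);
slowing regions scale displacements of cells inside them.

**Self-generated gradients.** Fields flagged degradable lose
`degradation_rate·Δt` (0.5 min⁻¹ cell⁻¹) at nodes within a sensing
radius of each metabolically active cell (DAMAGED/APO cells do not
consume). Dense regions dig deeper pits, so even an initially flat field
develops steep local gradients at the boundary between occupied and free
areas. In the wound scenario the flat long-lived "serum factors" field is
deposited together with the scratch — the cell-free band then stays rich
while the layer is consumed, which is what creates the persistent
edge-directed gradient — plus a short-half-life (4 h) "debris" field
inside the band.

## Events

`update`, `mediumChange`, `moleculeAddition`, `gradientAddition`,
`constraintAddition`/`constraintRemoval`, `scratchOnPlate`,
`transfection`, `viralInfection`. A scratch marks band cells DAMAGED at
damage 1 (they then overwhelmingly die, via the damage-resolution path,
leaving time for debris signalling) and deposits the debris field.
Transfection adds a gene to each live cell independently with the stated
efficiency. Infection arms a per-cell lysis timer (default 9 h); on
expiry the cell dies and each neighbour within the burst radius is
infected with the stated probability — spread occurs at lysis only, not
by continuous shedding, producing stepwise plaque-growth waves.

## Motion analysis

The component estimator regresses each displacement on an intercept and
the unit vector of its predecessor: `d_t = b + p·û(d_{t−1}) + r_t`.
Because the random term is independent of the regressors, ordinary least
squares recovers the bias vector and persistence module consistently even
though û correlates with b; the random module is the mean residual
length, matching the generator's mean-resultant calibration, so
generation → estimation round trips are consistent in expectation (the
binding design requirement; verified to <10% relative error at 50 cells
× 72 frames across the parameter grid). A rank-deficient design (all
previous directions identical) is unidentifiable between bias and
persistence; the estimator then attributes everything to bias
(persistence 0), the natural reading of a perfectly straight population.
Negative persistence estimates are floored at 0.

MSD uses all start frames (overlapping windows) with pair counts kept as
fit weights. The power-law and Fürth fits are weighted nonlinear least
squares (`scipy.optimize.curve_fit`, σ ∝ 1/√n_pairs); the Fürth fit
flags solutions at the parameter bounds. rMSD — the MSD attributable to
the random component alone — is defined as `steps·10·(rand/c)²` with c
the ten-step calibration constant, i.e. the exact MSD of the pure
random-walk generator at the estimated module. Displacement densities
use a Gaussian KDE with normal-reference bandwidth on a 25×25 grid.
Component contributions average, per overlapping window (default stride
one interval), the projections of each realized component vector onto its
displacement direction; the three contributions sum exactly to the mean
displacement module.

The track file dialect is this package's own plain-text format (header
with frame interval and optional pixel scale, per-cell blocks of
`time x y` rows with origin/destiny labels); readers reject malformed
input with a line number rather than repairing it.

## Synthetic data and what passing tests show

All test inputs are generated programmatically: three-component track
generators with known moduli, straight/Brownian paths, and integrated
Ornstein–Uhlenbeck paths (exact discretization) whose ensemble MSD
follows the persistent-random-walk law exactly — these provide
closed-form oracles for the estimator and the fits. They emulate the
*statistical structure* of tracked cell data, not its artefacts: no
tracking noise, no missed frames, no cell collisions merging tracks, no
finite-pixel quantisation. Passing round trips therefore demonstrate
estimator correctness under the model, not robustness to real tracking
errors. Similarly, the simulated populations reproduce calibrated
population-level statistics; individual parameter values should not be
read as measurements.

## Problem sizes

Reference runs use 100 starting cells for 3–5 simulated days at 20-min
intervals (growth, starvation), four seedings of 1–50 cells per
0.58 mm² for 15 days (stationary state), 50 cells × 72 frames for motion
round trips, and an ~600-cell confluent layer for 13–24 h wound runs —
the packaged scenario defaults, chosen to keep each experiment at
desk scale (seconds to a few minutes) while leaving the measured
fractions' sampling noise well inside the asserted bands.

## Known limitations

2-D only; cells are points (no shapes, no mechanical pushing — crowding
acts through statistical confluence, not contact forces); fields do not
diffuse; infection is single-strain, burst-only; the attachment surface
law and reporter kinetics are phenomenological; the parameter library
contains a single calibrated fibroblast-like type (plus a Vero-like
variant differing only in motility) rather than a measured panel.
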