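# Methods

This note documents the models and procedures implemented in `reachbias`,
the choices made where the design was genuinely open, and what the
synthetic cohorts do and do not establish.

## Task geometry and the distortion map

All computation is in millimetres in a screen-centered frame (x rightward,
y upward); pixels exist only at the I/O boundary through
`ScreenCalibration` (one px/mm ratio per axis, as obtained by measuring
500-px calibration lines).

The distortion rotates the drawn line about the trial's start position by
a fixed angle θ ∈ {−20, −10, 0, +10, +20}°. The sign convention is
direction-relative: positive θ pushes the line to the *right* of the
movement direction, negative to the left. In screen coordinates that is a
clockwise rotation, `line = R(−θ)(mouse − origin) + origin`. This single
global convention reproduces all eight per-trajectory deviation
directions (A: right/left; B and D: up/down; C: down/up), which are
locked in as unit tests on the default layout's start-direction vectors.
Compensation is the exact inverse: the mouse position whose line lands on
the target is the target rotated by +θ about the origin.

Only the four dot-pair chord lengths (351, 269, 351, 210 mm) and the
quadrant/side descriptions of the six dots are part of the published
design; the dot coordinates themselves are configuration. The default
layout hand-places the dots so every chord is exact by construction
(start dot + length × unit direction) inside the 950 × 550 mm display
area, with each dot in its described quadrant. Explicit coordinates can
be supplied (YAML or dict) and are validated against the chords unless
checking is disabled.

## Trial schedule

A session fully crosses 4 trajectories × 5 distortions × 2 cue conditions
× 4 repetitions = 160 experimental trials in random order. Every trial
starts on the dot where the previous one ended, so each gap between
consecutive experimental trials is bridged by 1 or 2 filler trials drawn
over non-experimental dot pairs; a gap whose endpoints coincide, or whose
direct connection would be an experimental pair, is forced to 2 fillers
through an intermediate dot. Fillers get uniform random distortion and
cue and are excluded from analysis.

The 303-filler session (463 trials) reported for the original design is
one random realization, not a rule; the generator's default is an
independent 1-or-2 draw per gap (total in [159, 318]), with an optional
exact total. The schedule begins directly with the first experimental
trial — whether leading fillers were allowed is unstated, and starting
with the experimental order keeps the gap arithmetic exact. The session
is split into two blocks at the midpoint of the trial list.

## The synthetic participant

There is no published participant model, so the simulator is the
package's own construction: the minimal closed-loop controller that
produces (i) distortion-compensating curvature and (ii) a
cursor-visibility effect of tunable size, so the analysis has a ground
truth to recover. Per step, from the position sensed `delay` steps ago
(default 2), the controller forms

- the corrective heading toward the compensated aim point (target rotated
  by +θ), and
- the naive heading straight at the target — where the visible cursor
  "wants" to go;

blends them with weight `b_eff` toward the naive heading, smooths the
blend into the running heading with fraction `gain`, and takes a step of
length ~ Normal(speed_mean, speed_cv · speed_mean) truncated at zero,
plus isotropic Gaussian motor noise. The trial ends when the *line* tip
enters the hit radius of the target (default 5 mm), or at a step cap of
10× the straight-line step count (recorded as a miss and excluded
downstream).

The cursor attraction applies only on cursor-visible trials and saturates
with the remaining distance `err` to the aim point:

    b_eff = cursor_bias_w · err / (err + bias_taper),   bias_taper = 50 mm.

Far from the goal the cursor pulls at its full weight; close in, line
feedback dominates — necessarily so, because the trial cannot end until
the line hits the target. A constant weight would instead create a
stalling equilibrium between the two aim points (where the corrective and
naive unit headings are antiparallel), leaving strongly biased distorted
trials unable to finish; the saturating form removes that equilibrium for
all weights up to ≈ 0.7 while preserving the intended mid-movement bias.
At θ = 0 the two headings coincide and the cursor has no effect, matching
the design's control condition.

Cohort defaults (uniform ranges per subject) are chosen as plausible for
a seated adult moving a mouse over ~20–35 cm reaches: `gain` 0.5–0.7,
`cursor_bias_w` 0.3–0.6, `noise_sd` 0.5–1.0 mm/step, `speed_mean` 6–10
mm/step at ~60 Hz sampling (≈ 360–600 mm/s), `speed_cv` 0.3–0.5, delay 2
steps (≈ 33 ms). Each subject also draws a lateral aim offset
~ Normal(0, 2 mm) applied to both aim points, giving the cohort true
between-subject variance for the mixed model's random intercept.
Timestamps advance by 16 ms ± 25% jitter, so recording is time-driven and
spatial sample spacing varies with speed — which is what makes the
interpolation step meaningful.

## Normalization, mirroring, binning

Each analyzed trajectory (the mouse/hand stream by default; the line
stream is selectable — the published results discuss the hand movement)
is (1) translated so the origin dot is at (0, 0); (2) rotated about the
origin so the destination dot lies at (0, L); (3) resampled evenly in arc
length (default 0.1 mm, with the original vertices kept in the grid), and
x read at each integer millimetre of y. Interpolation is piecewise linear
in arc length — the simplest faithful reading of "evenly distributed
along the trajectory"; movements can backtrack in y, so each y level
takes the *first* crossing along the path, and levels never crossed are
flagged missing rather than imputed.

x values of negative-distortion trials are multiplied by −1 (mirrored
about the y-axis) so deviations are comparable across distortion signs;
the signed distortion label is retained for grouping. Per-mm samples are
pooled into half-open 10-mm bins [10k, 10(k+1)); bin 0–10 is discarded,
as is a trailing bin not fully inside the trajectory. This yields 34 bins
at 351 mm, 20 at 210 mm, and 25 at 269 mm. For the 269 mm trajectory a
threshold of 0.05/26 is also quoted in the original report, implying a
26th (9-mm partial) bin; both behaviours are reachable
(`include_partial_bins=True` retains partial bins at least 5 mm wide),
and the package defaults to the stated discard rule without guessing the
intent. Floors near integer boundaries use a 1e-9 tolerance so a chord
recovered as 350.999…9 mm after rotation still yields 351 levels.

## Per-bin mixed models and contrasts

For each retained bin of one trajectory, the pooled per-mm x values are
modelled as `x ~ C(cue, Sum) * C(distortion, Sum)` with a random
intercept per subject, fit by REML (statsmodels MixedLM; optimizer
fallbacks BFGS → Powell → L-BFGS, then a zero-variance OLS fit with a
warning if none converges; a boundary fit is flagged singular but kept).
Distortion is categorical — the per-level post hoc reporting requires it.
Post hoc, the biased − unbiased marginal difference is estimated at each
distortion level by a fixed-effect contrast with a Wald z p-value
(no degrees-of-freedom approximation is claimed by the original
analysis), Bonferroni-multiplied by the per-bin family of 5 distortion
levels (configurable to other family sizes), capped at 1, and compared
against the trajectory-level threshold 0.05 / n_bins. Maximal contiguous
spans of significant bins are reported per distortion level; bins with
inestimable models break contiguity rather than being bridged.

A known property of this design, faithfully reproduced: pooling per-mm
samples treats within-trial readings as independent although they are
strongly autocorrelated, so per-bin standard errors are optimistic and
isolated significant bins appear even at 0° distortion. The calibration
check in the test suite therefore simulates genuinely exchangeable null
data (subject offsets + iid noise), where the contrast's type-I error is
nominal (≤ 0.07 at α = 0.05 over 1000 simulations).

With zero random-effect variance the mixed model reduces to OLS on the
same design, and because the cue × distortion model is saturated, every
contrast equals the observed biased − unbiased cell-mean difference; the
test suite verifies this against a hand-computed cell-means oracle to
1e-6 mm, independent of statsmodels.

## What the synthetic cohorts show — and what they do not

The end-to-end check (20 subjects, cursor-bias weight fixed at 0.5)
recovers the intended signature: positive biased − unbiased estimates
with significance runs through the final third of bins at every nonzero
distortion, and mean estimates near zero at 0°. This validates the
*pipeline* — that the preprocessing and per-bin models detect a
cursor-driven compensation deficit of the simulated kind with the right
sign and spatial profile. It does not validate the controller as a model
of human motor control: real participants show learning suppression,
speed–accuracy trade-offs, anticipatory strategies and body-referenced
asymmetries (e.g. trajectory-specific reversals) that the simulator does
not attempt; numeric estimate ranges from human data are therefore out of
scope. Simulated effect sizes (≈ 8–25 mm late-bin differences at weight
0.5) are deliberately larger than the 1–9 mm reported for humans; the
weight can be dialled down for power studies.

## Problem sizes and determinism

Default study-scale conditions are 53 subjects × 160 experimental trials;
the validation suites use scaled-down cohorts (6–20 subjects) that keep
the full condition crossing, and 1000-replicate null simulations at one
bin. All randomness flows through `numpy` Generators seeded from a single
integer (per-subject streams via `SeedSequence.spawn`), so schedules,
cohorts and analyses are bit-reproducible given a seed.
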