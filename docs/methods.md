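# Methods

## Task model

One trial of the anticipated-response-inhibition task is a bar that fills
linearly over `trial_duration` (default 1 s). The go response is a key
*release* timed to stop the bar at a target drawn at `target_fraction`
(default 0.8) of the bar height, i.e. at `trial_duration * target_fraction`
= 800 ms. Bar kinematics follow the two standard rendering formulas:
position = height · (elapsed / duration) (time approach) and distance per
frame = height · (frame time / duration) (space approach); both are exposed
because they are the task's only geometry and are trivially checkable
(5.055 cm at 0.337 s; 0.25 cm/frame at 60 Hz, defaults).

Go feedback is banded by the absolute error of the release time from the
target: ≤ 20 ms green, ≤ 40 ms yellow, ≤ 60 ms orange, > 60 ms red. "Within
20 ms" is read as inclusive (≤), each band half-open above its lower
threshold; the bands are symmetric about the target by construction. Band
severity is taken as green < yellow < orange < red.

A stop trial halts the bar at the SSD (ms into the trial). Any key lift
after fill onset and before trial end — even before the bar halts — is a
failed stop with its RT recorded (response has only two codes, so there is
no third category for "lifted before the signal"). Holding through the full
trial duration is a successful stop.

The default session is practiceGo (10 go), testGo (30 go), practiceMixed
(15 go + 5 stop), then three testMixed blocks of 60 go + 20 stop = 300
trials. Two independent toggles drop (a) both practice blocks and (b) the
go-only test block, mirroring the task's start-up checkboxes.

### Staircase

SSD tracking is 1-up/1-down: +`step_size` (25 ms) after a successful stop,
−`step_size` after a failed one, clamped to [`min_ssd`, `max_ssd`] =
[50, 775] ms. Go trials never touch the state. The staircase initialises at
`initial_ssd` (500 ms) for the practice mixed block, re-initialises at the
first test mixed block, and then carries across the remaining test blocks —
practice performance is recorded but never carried over. Arithmetic is plain
clamped addition; the step is not required to divide the distance to the
clamps (clamping absorbs remainders). In `fixed` mode each stop trial takes
its SSD from the condition table's `fixedStopTime` column; the value stays
attached to its table row through a random permutation of the block.

### Degenerate and edge inputs

A lift during the variable start interval (before the bar fills) aborts and
restarts the trial without consuming a trial index; the restart count is
recorded on the eventually completed trial. A lift within the first
`early_lift_window` (100 ms) of the fill is a *recorded* response flagged
for encouragement, not a restart — only the start-interval lift restarts. A
go trial with no lift before the bar fills is an omission (response 0, RT
undefined, red feedback). The variable start interval is uniform on
[0.5, 1.0] s — a bounded, seeded choice typical of anticipation paradigms;
its exact distribution cannot affect any analysis output because all times
are measured from fill onset.

## Race-model simulator

Each trial draws a go finishing time and, on stop trials, a stop latency,
both truncated-normal on (0, ∞). The response escapes iff
`t_go ≤ SSD + t_stop` (the go process wins ties — a measure-zero event under
continuous distributions, pinned so integer-ms test vectors are
deterministic) and `t_go ≤ trial_duration`. Truncated normals are the
simplest family whose location is the recovery target for the estimator;
ex-Gaussian finishing times would be a natural extension. Context
independence holds by construction: the go distribution is identical on go
and stop trials, which is the assumption the nonparametric estimator needs.
Trigger failures (stop process never launched; the race collapses to the go
process) and spontaneous start-interval lifts are first-class probabilities,
both defaulting to 0, so estimator bias under assumption violations can be
probed.

Default participant: go ~ N(0.80 s, 0.05 s), SSRT ~ N(0.20 s, 0.03 s). The
go parameters put the simulated release at the target with a few-percent
temporal jitter, the calibre of a practised adult on an anticipation task;
no empirical go-SD is pinned down for this task family, so these defaults
are plausibility choices, not fits. Under them the staircase's equilibrium
SSD is `go_mean − ssrt_mean` = 600 ms, safely inside the clamps.

One seeded `numpy` Generator drives a whole session; the draw order per
trial attempt is fixed (start-interval draw, start-lift Bernoulli, go time,
trigger Bernoulli, stop latency), so sessions replay bit-identically from a
seed. Cohort members get independent streams spawned from a master seed via
`SeedSequence`.

## Analysis

- **Go metrics**: mean/SD over responded go RTs; omission count; feedback-band
  proportions over all go trials (bands + omissions partition the trials).
- **P(respond | signal)**: failed stops / stop trials.
- **SSRT, integration method with replacement**: one `trial_duration` value
  appended per go omission; 1-based rank ⌈p·N⌉ of the sorted augmented
  sample; minus the mean SSD. The rank convention is pinned (and property-
  tested against an explicit sort-and-index oracle) so users can compare
  against other conventions; other toolchains may differ by one rank step.
  Undefined at p = 0 (returned as NaN with a flag, never a number).
  All estimator inputs — go RTs, omissions, p, mean SSD — come from the
  mixed *test* blocks only: practice is excluded, and the go-only test block
  feeds only the proactive contrast.
- **Inhibition function**: stop trials binned by SSD (default 50 ms bins,
  bin centres reported); empty bins omitted; a bin spanning all SSDs
  reproduces the overall P(respond | signal).
- **Proactive inhibition**: mean and SD go-RT differences, mixed test blocks
  minus go-only test block (positive = anticipatory slowing).
- **Plot bundles**: six per-participant tables (go descriptives, RT by trial
  with correctness, RT values by trial class for density plots, stop
  descriptives, SSD by trial, inhibition function). Rendering to an image is
  a thin optional matplotlib layer over the tables; the tables are the
  product.

No inferential statistics are produced — the module reports descriptives and
estimates. Bayesian parametric race-model fitting (e.g. for
context-independence violations) is out of scope.

## Data formats

Trial files are space-delimited `.txt` (tabs accepted on read) with columns
`id block trialType trial signal response ssd rt`; `signal` 0 = go /
1 = stop, `response` 1 = response made / 0 = none, undefined cells are the
literal string `NaN`. `ssd` is NaN exactly on go trials; `rt` is NaN exactly
when no response was made (correct stops and go omissions). **Both `ssd` and
`rt` are stored in seconds** for column symmetry, while `TaskParameters`
quotes SSDs in milliseconds — the conversion lives entirely at the I/O
boundary. The STOP-IT dialect is the same table without `trialType`; reading
it fills a uniform test label so both dialects analyze identically row for
row. File names are `ID_OSARI_yyyy_month_d_hhmm.txt` with the month spelled
out in English and the day unpadded. Validation is row-addressed: bad
signal/response codes, non-numeric cells and misplaced NaNs name the
offending row.

## What the simulator does and does not show

The generator emulates a stationary, context-independent race with
truncated-normal finishing times. Tests passing on it demonstrate that the
task logic, staircase, file formats and estimator chain are internally
consistent and that the estimator recovers known parameters under the
model's own assumptions. They do not show robustness to what real data add:
RT drift and fatigue, ex-Gaussian tails, context-independence violations,
or strategic slowing. Human-subject benchmarks (e.g. cross-task SSRT
correlations between ARI and choice-reaction tasks) are not reproducible in
simulation and are out of scope; the race model's testable signature —
signal-respond RTs stochastically faster than go RTs — stands in.

## Problem sizes

The staircase-calibration check uses 200 staircased stop trials per seed,
averaged over 20 seeds; parameter recovery uses 20 replicates of sessions
with 600 go + 200 stop trials; the monotone-inhibition check uses 500 trials
per fixed SSD; the estimator/oracle equivalence uses 1000 randomized small
inputs (n ≤ 50). These sizes make the stochastic checks stable at the
tolerances stated in the tests while keeping the whole suite fast on one
CPU.

## Known limitations

- No rendering, keyboard capture or frame timing: the geometry functions
  document the stimulus math but nothing is drawn.
- The staircased SSRT convention (rank ⌈p·N⌉, omissions → trial duration,
  test-block-only inputs) is documented, not asserted identical to any other
  toolchain's variant.
- Finishing-time distributions are truncated-normal only.
- The file format stores times in seconds with 6 significant digits; exact
  bit-level round-tripping holds to that precision.
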