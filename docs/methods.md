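# Methods

This note documents the models, conventions and numerical choices
behind `larvalearn`, and what the synthetic-data tests do and do not
demonstrate.

## Coordinates and session model

Arena coordinates are centimeters, origin at the bottom-left corner, y
up; the midline is y = 1.5 cm in the default 3 × 3 cm arena. Headings
are degrees counterclockwise from +x, wrapped to [−180, 180). Tracks
are sampled at 10 Hz and stored column-wise; the YAML session schema
(top-level keys `metadata` / `phases` / `track` / `patterns` /
`shocks`) is self-defined — the original acquisition software also
logged YAML, but its layout is unpublished, so no file-level
compatibility is claimed. Floats are rounded on write (timestamps to
0.1 ms, positions to 0.1 µm), making write→read a field-by-field
identity at those tolerances.

## Protocol engine

The engine is stepped once per frame with the fish's current CS-zone
membership (head-based; a head exactly on the midline counts as
non-CS) and advances an integer frame counter, so phase boundaries are
exact — accumulating the 0.1 s step in floating point drifts enough
after 18 000 frames to misassign a frame across a phase boundary.

Training-phase semantics, with timers carried between frames:

- every pattern update (including the one at training start) opens a
  7 s no-shock decision window;
- after the window, a fish in the CS zone is shocked on the current
  frame and then every 3 s while it remains; a fish *entering* the CS
  zone later in the same pattern interval is shocked immediately on
  entry (the zone-contingent reading of "shocked until escape");
- the 48 s non-CS dwell timer accumulates over frame intervals labeled
  by their end frame, resets on every CS-zone visit and on every
  pattern update, and triggers a pattern re-randomization (top/bottom
  with probability ½) when it reaches 48 s.

Baseline flip intervals are drawn uniformly from [30, 45] s and floored
to the frame grid, so realized intervals stay inside the stated range;
test-phase flips alternate every 120 s from test start. The first CS
side of each phase is drawn with probability ½ (unstated in the
protocol description). The unpaired variant replaces closed-loop shocks
with `n` times drawn uniformly over the training window under a minimum
3 s gap (sorted-uniform construction on the gap-compressed interval,
which is the exact uniform law on the constrained set); `n` defaults to
40, matching the order of magnitude of closed-loop shock counts in
paired simulations — the source protocol does not state it.

## Virtual larva

The simulator is a stand-in for live fish: the assay's learning
mechanism is unobservable, only its behavioral read-outs are defined,
so the agent carries a latent avoidance memory `A ∈ [0, 1]` whose
*behavioral* consequences the pipeline must recover.

- **Memory.** Shock: `A ← A + η(1 − A)` (default η = 0.25 for
  learning-capable agents, 0 for controls). Test phase, no shock:
  `A ← A·e^{−λ·dt}` (default λ = 0.002 s⁻¹). Extinction decay runs only
  in the test phase, where the assay measures it.
- **Locomotion.** Bouts start at exponential intervals (rate
  2.2 s⁻¹), turn the heading by a Gaussian (σ = 40°), and displace the
  fish by a Gamma(2)-distributed step (mean 0.55 cm ≈ 1.4 body
  lengths) played over three frames; between bouts the fish drifts
  with 0.04 cm/frame isotropic jitter. Walls are reflective (with the
  drift direction redrawn every frame so wall contact cannot fake a
  frozen run). Freeze episodes (probability 0.004 per bout, duration
  1 s + Exp(2 s)) produce the stationary runs the pre-screen is meant
  to catch.
- **Directional bias.** Each bout heads toward the non-CS half with
  probability `clamp(½ + b_p·(−contrast/128)·𝟙[CS darker] + b_a·A,
  0.05, 0.95)` (defaults b_p = 0.03, b_a = 0.4); the heading is
  mirrored across the x-axis when its vertical component disagrees
  with the chosen half, which makes the realized per-bout choice
  exactly that Bernoulli probability. The phototaxis term vanishes at
  zero contrast (white-black checkerboard), mirroring the
  contrast-not-structure dependence of the learning effect.
- **Pose.** Head and tail are laid out half a body length (default
  0.4 cm, a typical 7–10 dpf larva) fore and aft of the center along
  the heading.

The kinematic defaults were chosen so that the virtual fish mixes
across the arena well within one 2-min epoch (mean speed ≈ 1.2 cm/s,
occupancy relaxation a few seconds). This matters statistically: with
slow mixing, the 30–45 s baseline intervals spend proportionally more
time re-equilibrating after each flip than the 120 s test intervals,
which systematically depresses baseline positional indices relative to
test ones and would manufacture learners out of control fish — an
artifact of a sluggish agent, not of the assay. With the defaults the
null baseline-vs-test shift is ≈ +0.02, inside epoch noise.

What the simulator does **not** model: visually guided swim kinematics
(O-bends, J-turns), thigmotaxis, startle responses to shock onset,
between-fish parameter heterogeneity, or any dependence of learning
rate on contrast. Passing recovery tests therefore shows the pipeline
is correct and well-calibrated on data with the assumed structure, not
that real fish behave this way.

## Tracking

`render_fish` draws two identical anisotropic Gaussian body lobes
placed symmetrically about the center along the heading, plus a small
low-mass bright dot on the head side: the intensity-weighted centroid
of the blob is the fish center by construction (head dot displaces it
< 0.15 px) while the head end stays the brighter one. `track_frame`
thresholds (Otsu by default — no threshold is prescribed), requires
exactly one connected component of plausible area (≥ 12 px; anything
else raises a detection error — frames are flagged, never fabricated),
and estimates: center = intensity-weighted centroid; body axis =
principal axis of the second central moments; head/tail = extremal
component pixels along the axis; heading = axis direction signed
toward the brighter end. Side brightness is compared only beyond 2 px
from the centroid, because the two body lobes overlap at the midpoint
and the grid pixel holding that maximum falls on a random side. When
the side-peak ratio is below 1.05 the frame is ambiguous and the
orientation closer to `prev_heading` is kept. Closed-loop accuracy
over 500 random noisy poses: median heading error ≈ 0.7° (max < 5°),
median center error ≈ 0.16 px.

A turning event is a wrapped heading change strictly greater than 15°
between consecutive frames, computed on the circle (179° → −179° is a
2° change); exactly 15° is not an event.

## Behavioral metrics

- **Frozen frames / pre-screen.** A frame is stationary when the
  center moved < 0.02 cm since the previous frame (the displacement
  floor operationalizes "did not move", which is otherwise
  unquantified; 0.02 cm is sub-pixel at plausible optics). A maximal
  stationary run marks its frames frozen iff it spans strictly more
  than 1 s. Data quality = fraction of non-frozen frames; sessions
  below 0.95 are excluded (exactly 0.95 is kept).
- **Positional index.** Fraction of in-window frames with the head in
  the non-CS half under the pattern active at that frame. Frozen
  frames are retained (occupancy is meaningful while frozen).
- **Turn scoring.** An escape turn requires band entry (within
  2 × body length of the midline) from the non-CS side, ≥ 1 turning
  event inside the band, and band exit away from the midline without a
  crossing; a crossing into the CS zone scores −1; CS→non-CS crossings
  are unscored. Frozen frames are excluded from turn scoring; a
  pattern flip resets any episode in progress. The turning index is
  undefined (NaN, excluded from means) when both scores are zero.
- **Epochization.** Contiguous 120 s epochs over baseline, training
  and test (phase durations must divide 120 s; the blackout is
  excluded), giving 24 epochs (5/10/9) under the default plan.

## Learning analysis

Baseline = mean positional index over baseline epochs. Extinction
point = first test epoch strictly below the baseline (1-based); memory
length = (epoch − 1) × 120 s, or the full 1080 s test when no epoch
drops below (flagged `no_extinction`); categories: short [240, 500) s,
mid [500, 1000) s, otherwise no-extinction (recall periods shorter
than two epochs are labelled `sub_threshold` and can never classify as
learners).

**Learner test.** Recall-period per-epoch positional indices against
baseline per-epoch indices, Welch's unequal-variance two-sample t-test,
learner iff p < 0.05 *and* the recall mean exceeds the baseline mean,
with recall ≥ 2 epochs. Per-epoch indices are the unit of observation —
the only within-fish replicates the epochization provides. The
directional requirement is implemented as two-sided significance plus
sign rather than a one-sided test: because recall epochs are by
construction at or above the baseline mean (epochs below it terminate
the recall period), a one-sided test at α doubles the procedure's null
learner rate (~8–12% in Monte-Carlo replays of the rule on iid epoch
noise), while the two-sided-plus-sign form keeps it at ~α. This also
matches the plain reading of "the unpaired t-test" in the assay
description (conventional t-tests are two-sided by default).

`pi_increase` / `ti_increase` are recall-mean minus baseline-mean of
the respective index. No multiple-testing correction is applied by
default (raw p-values are reported, as in the source analysis); a Holm
correction utility can be layered by the caller.

**Group extinction.** On the learner-mean test-phase curve: PI₁ = first
local maximum (the first epoch counts if it exceeds its successor;
plateaus resolve to the earliest epoch), group extinction point = first
mean-curve epoch below the learner-mean baseline, PI₂ = the local
minimum nearest that point (ties to the earlier epoch), rate =
(PI₁ − PI₂) / memory length in minutes. The group-level curve (not the
mean of individual memory lengths) defines the memory length here;
`group_extinction` exposes the curve so callers can compute
alternatives. A flat never-extinguishing curve yields rate 0 over the
full test duration.

**Group tests.** Paired t-test of per-fish baseline vs recall means
within a cohort (exactly identical phases short-circuit to p = 1
rather than a 0/0 statistic); Welch unpaired t-test of per-fish index
increases between a conditioned cohort and a control cohort.
Percentages of learners are reported rounded to integer percent.

## Problem sizes and determinism

All randomness flows from `numpy.random.Generator` seeds;
`simulate_cohort` spawns one independent substream per fish
(`SeedSequence.spawn`), so cohorts are bit-reproducible and fish are
order-independent. Recovery tests use cohorts of 40 fish (and 3 × 16
for the extinction-decay sweep) at the full 49-min, 10 Hz session
length — about 30 s of simulation per 40-fish cohort — which keeps the
planted-fraction binomial interval meaningfully narrow while the whole
suite stays fast. The classifier's null rate is checked against
α + 2·binomial-SE on a self-control cohort; given the ~5% procedural
floor described above, cohorts occasionally realize 10% — the test
seed is fixed, and multi-seed behavior (6–7% across 8 seeds) is
documented here rather than asserted.

## Known limitations

- The extinction-rate peak/valley detection uses first-difference sign
  changes; heavily oscillating mean curves can place PI₂ on a local
  wiggle rather than the visually obvious valley.
- The tracker is validated only against its own synthetic renderer;
  the original acquisition pipeline's head/tail estimation method is
  undisclosed, and real dark-field frames (eye glare, tail flex,
  reflections) would need re-validation.
- Learner percentages, extinction rates and memory lengths measured on
  simulated cohorts characterize the pipeline, not live fish; the
  published biological rates depend on unreleased recordings and are
  deliberately not targeted.
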