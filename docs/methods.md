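# Methods

## The quantity space

The environment is an abstract two-dimensional "quantity space".  A
position is a pair of shape counts `(q1, q2)` — e.g. the number of circles
and the number of rectangles shown on screen — each axis running from 0 to
`axis_length = 200` *conceptual meters* (one meter = one shape).
Dimension-specific filler triangles pad every view to `total_items = 400`,
so `n_shapes + n_fillers = 200` per dimension and visual complexity is
constant across the space.  Positions are continuous internally; integer
item counts exist only at render time (round-half-up; the rounding rule is
a display choice that no analysis depends on).

Heading is colour-coded rather than conveyed by optic flow.  With the
heading angle θ measured counter-clockwise from the +dim-1 axis, the
dimension-1 items are coloured by cos θ and the dimension-2 items by
sin θ on a blue (−1, quantity will decrease) – purple (0, no change) – red
(+1, increase) scale.  We use the linear RGB map `(0.5(1+v), 0, 0.5(1−v))`;
the constant channel sum R + B stands in for the luminance matching of the
real stimuli.  Exact endpoint RGB values are config constants because no
analysis consumes them.  Movement smooths translational velocity over
`smoothing_frames = 4` frames at `frame_rate = 90` Hz (a 0.044 s window) and
clamps positions to the square.

Which shape (circles or rectangles) is assigned to dimension 1 is a
per-participant flag, counterbalanced by the cohort generator.

## Visual similarity

Two positions share items to the extent their *category totals* agree.  We
count overlap in two pooled categories — all target shapes and all fillers:

    overlap(a, b) = min(q1a + q2a, q1b + q2b) + min(Fa, Fb),
    F = total_items − q1 − q2.

On a circle of radius 100 m around the centre, min–max scaling of the
overlap gives the angle-only profile

    sim(θ) = 1 − |cos θ + sin θ| / √2,

with maxima at 135°/315° (one quantity traded for the other; category
totals unchanged) and minima at 45°/225° (both quantities rise or fall
together).  **Pooling convention:** a four-category overlap (each shape and
each filler kind counted separately) would instead equal `total_items −
L1-distance`, whose extrema lie on the axes.  Only the pooled two-category
count makes 135°/315° the maximally similar directions, which is what the
forced-choice design requires, so that is the convention implemented; the
verbal definition "total amount of items shared" alone does not
disambiguate it.  The profile is tabulated on a 1° grid and linearly
interpolated on the circular axis.

## Task protocols

All generators are pure functions of `(seed, config)`.

**Navigation training.**  5 "notify" trials (automatic arrival notice when
within 10% of the axis — |Δq| ≤ 20 — on *both* dimensions), 3 "press"
trials, then self-paced test trials.  Goals are uniform over the space, at
least 30 m from the start; navigation is continuous (each start is the
previous indicated goal).  The gamepad group (GG) runs exactly 28 test
trials; the movement group (MG) runs to a 54-minute task-time budget with a
minimum of 14 test trials.  Because the trial count of a time-budgeted
session cannot be known at generation time, MG specs are generated as a
pool of 40 that the simulator consumes until the budget is spent.  Feedback
on press/test responses: error % = 100·d/(200√2), 5%-wide bins each
dropping one point from a 20-point maximum (`points = max(0, 20 −
⌊error%/5⌋)`).  Message classes are four labels on error-quartiles; the
thresholds are our choice, as only the existence of graded messages is
specified.

**Distance/direction estimation.**  3 practice trials, then a 4 × 9
factorial (distance bin × direction bin), each cell once — 36 test trials
in 4 blocks of 9.  Distance bins are four equal-width intervals over
20–180 m ([20,60), [60,100), [100,140), [140,180]; only the range and bin
count are prescribed, equal widths are our choice), direction bins 40°
wide.  All test positions keep ≥ 10 m from each other and from the axis
limits (rejection sampling with a bounded retry budget).  Distance
responses live on a 29-increment slider (positions 0–28) spanning 0 to the
time needed to traverse the diagonal; at constant speed the map to distance
is linear, `d = pos/28 · 200√2`, initialised at the centre (position 14).

**Forced choice.**  216 test trials + 5 practice, two intermixed sub-tasks
in 4 blocks, 5 s limit per trial, all three positions of a trial in one
colour code.  *Similarity sub-task* (96 trials): goal 90–100 m from the
axis limits per dimension (distance-to-nearest-limit uniform in [90,100],
side at random); one option distorted 10 m along a maximally-similar
(135°/315°) or maximally-dissimilar (45°/225°) direction, the other by 60,
90 or 120 m along the opposite condition; 16 repetitions per (far distance
× condition) cell; colour codes 45° or 225°, and on dissimilar-correct
trials half aligned / half misaligned with the correct option's true
direction.  *Dimensional sub-task* (120 trials): goal 4–10 m from the
limits in the lower-left or upper-right corner; one option distorted 5 m in
one shape dimension, the other 15, 30 or 55 m in the alternate dimension
(margins 10/25/50 m); 60 trials per corner, 10 per distance scenario;
colour 135°/315° with ±10° jitter.  Practice trials are flagged and
excluded from all analysis by default.

## Synthetic participants

No generative model of behaviour is claimed; the agents are statistical
stand-ins whose logs carry exactly the structure the pipeline is meant to
detect, one parameter per effect:

* **Goal placement.**  Per trial the agent commits to one goal percept
  `G* ~ N(goal, σ²)` with `σ = goal_sd · e^(−learning_rate·k) · (1 +
  boundary_gain · d_border/(L/2))`, where `k` is the test-trial index and
  `d_border` the goal's distance to the nearest wall.  The response is
  placed at `G*`, so learning shrinks errors over trials and
  `boundary_gain > 0` makes border goals easier (negative
  border-distance/accuracy correlation).
* **Walking.**  The agent steps at `dt = 0.5 s` toward transient aim points
  `~ N(G*, (wander_sd · e^(−learning_rate·k))²)` redrawn every 2 s, with
  von-Mises heading noise and speed `~ N(speed_mean, speed_sd²)`; it homes
  in exactly once within 4 m of `G*`.  After each full second of movement
  it pauses (7 s) with probability `pause_prob`; goal retrievals, hints
  (training only) and rare long breaks are logged as events.  The 0.5 s
  step is a deliberate scale-down of the 90 Hz display loop: the analyses
  consume segment geometry and event durations, not frame-rate detail.
* **Estimation.**  Slider distance `= α + β_d·d − similarity_bias·sim(θ) +
  ε`, snapped to the 29 increments; visually similar directions are judged
  closer.  Direction estimate = true angle + wrapped-normal noise with
  `sd = dir_sd0 · (1 − dir_distance_gain · d/d_max)`, so angular error
  shrinks with distance.
* **Forced choice.**  Every coordinate of A, B, C is perceived with
  multiplicative Weber noise (sd `= w · max(q, 20)`, dimension-specific via
  the shape assignment), so small corner quantities are easier to compare
  than large ones; options are compared on perceived distance minus
  `similarity_bias · sim`, through a logistic rule with temperature
  `decision_temp` (0 = hard argmin), a `lapse_rate` of random responses and
  rare timeouts.  The post-training run scales perception noise by the
  learning factor accumulated over 28 navigation trials.

**Defaults.**  The defaults define the simulated study conditions and were
set once to land the cohort-level summaries near the values the protocol
was designed around: mean test-trial durations ≈ 115 s (MG, which then
completes ≈ 24 trials under the 54-min budget) and ≈ 86 s (GG, fixed 28
trials) via group pause rates 0.53/0.42; mean movement speed ≈ 9 m/s; mean
accuracy ≈ 0.86 and excess path ≈ 1 (`goal_sd = 38`, `wander_sd = 25`,
`boundary_gain = 0.6`); distance-estimate correlations ≈ 0.5
(`est_beta_d = 0.9`, `est_noise_sd = 70`); mean absolute angular error
≈ 45° (`dir_sd0 = 70°`, gain 0.6); forced-choice accuracy modestly above
chance.  The GG template carries a mild Weber asymmetry (circles 0.125 vs
rectangles 0.085), giving it a dimensional bias the MG lacks.  Per-agent
seeds derive from one master seed via `numpy.random.SeedSequence` spawning;
reruns are byte-identical.

**What the generator does *not* emulate.**  Human response-time
distributions, fatigue, strategy switches, inter-individual parameter
correlations, or flat accuracy across trials (our learning factor improves
accuracy slightly, whereas free goal viewing kept human accuracy flat).
The corner effect in the dimensional sub-task is strong here by
construction of the Weber noise, and the dimensional bias is small because
both dimensions enter every comparison.  Passing tests therefore show that
the *pipeline* recovers known structure from logs of the documented format
— not that the agent model describes human navigators.

## Behavioural measures

* **Accuracy**: fraction of 1000 uniform random positions strictly further
  from the goal than the response (ties count as not further; a
  measure-zero choice).  Chance is 0.5; a response at the null's 5th
  percentile scores 0.95.  Null draws are seeded per (agent, trial).
* **Excess path**: (taken path − straight start→goal)/straight.  The
  origin is the first logged position — the realized start — because trials
  chain at the previous *indicated* goal; this keeps the ratio ≥ 0 exactly.
* **Navigation time**: response time minus trial start minus goal-view and
  break durations.  Whether hint viewing is also excluded is ambiguous in
  the protocol (it is excluded from speed segments); the default keeps it,
  `exclude_hint=True` removes it.
* **Segment speed**: trials split into continuous-movement segments;
  goal/hint viewing, breaks and stationary periods (speed < 0.1 m/s for
  ≥ 1 s — "stationary" is not quantified in the protocol, so the threshold
  is config) end a segment; segments covering ≥ 10 m contribute their mean
  velocity; the unweighted mean over segments is reported and a participant
  with no valid segment is marked excluded.
* **Dimensional errors**: mean |Δq| per axis, mapped to circles/rectangles
  through the participant's dimension assignment.
* **Angular error**: minimal circular absolute difference (chance 90°).
* **Border correlation**: per-participant Pearson r of trial accuracy with
  goal border distance; zero-variance input yields an NaN marker that the
  group test drops with a warning.

## Inference

Two-stage scheme: OLS (with intercept) per participant, the regressor's
t-statistic carried to a sign-flip permutation test of the group mean
(10,000 flips default).  The p-value is the proportion of permuted means at
least as extreme as the observed one, floored at 1/n_perm — so the smallest
p at 10,000 permutations is 0.0001 and its z-equivalent Φ⁻¹(1−p) = 3.719.
Perfect per-participant fits have unbounded t; they are winsorized at 10⁶
and flagged rather than propagated as infinities.

Classical tools: two-sample comparisons default to Welch (the protocol's
fractional dfs are Welch–Satterthwaite values); Bayes factors are JZS with
a Cauchy(√2/2) prior on effect size, computed via pingouin and
cross-checked in the tests against an independent dense-grid quadrature of
the same integral; group tests on Pearson correlations use the raw r scale
(no Fisher transform, matching the convention of testing "mean r"
directly).  The power solver iterates n upward until the noncentral-t power
reaches the target; one-sample, one-sided, d = 0.5, α = 0.05, power = 0.95
gives n = 45 per group.

The mixed ANOVA is implemented in-package because no installed library
covers one between factor with several within factors: balanced univariate
sums of squares by inclusion–exclusion over cell totals, each within effect
tested against its interaction with subjects-within-groups (equivalent to
type-III/sum-to-zero on balanced data), with Greenhouse–Geisser epsilon
from pooled within-group contrast covariance when an effect has more than
one numerator df.  All factors in this protocol have two levels, so the
correction is the identity there; a constant dv yields F = 0 by convention.
It is validated against base-R `aov` error strata (frozen oracle values),
against `pingouin.mixed_anova` on one-within designs, and against the
paired-t identity F = t².  Designs must be complete and balanced; anything
else raises an error rather than silently reweighting.  Bonferroni pairwise
post-hocs report both raw and corrected p.  Outlier exclusion is not
applied anywhere by default (exclusions are reported not to change
conclusions in this protocol); the metric tables make custom filtering
trivial.

## Problem sizes and tolerances in the test suite

The acceptance checks run the pipeline at the study scale where it matters
and a smoke scale where it does not: full-pipeline effect recovery uses 45
agents per group with 1000 permutations and 500-point accuracy nulls;
type-I calibration uses 500 replicate null cohorts of 20 agents with 250
permutations each, checked against the binomial 95% interval around
α = 0.05 and a KS distance to uniformity; Monte-Carlo chance levels use
10,000 draws (tolerances ±0.01 on accuracy, ±2° on angular error, the
Monte-Carlo standard error with headroom).  Floating-point geometry is
asserted to 1e-9 where exact, and statistical oracles (R aov, quadrature
Bayes factors) to the precision they were computed at.
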