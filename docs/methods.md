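# Methods

This note documents the models, conventions and numerical choices behind
`mazemetrics`: what each metric assumes, what the synthetic navigators
emulate (and deliberately do not), and the decisions made where the design
was genuinely open.

## Coordinates and preprocessing

All analysis happens in an arena-centered right-handed Cartesian frame in
virtual meters, yaw in radians counterclockwise from +x. Recordings made in
engine conventions (e.g. a left-handed y-up frame) are mapped on load: the
reader accepts a 2×2 `axis_map` for positions, and the quaternion→yaw
converter has an explicit convention switch (`z_up` uses
`atan2(2(wz+xy), 1−2(y²+z²))`; `unity_y_up` extracts the rotation about the
vertical y axis and flips the sign so counterclockwise-from-above is
positive). Correctness is checked against rotation-matrix extraction on
random unit quaternions.

The yaw channel is unwrapped first and filtered second. Filtering a wrapped
angle would smear the ±π discontinuities into spurious angular velocity;
unwrap-then-filter makes the channel continuous before any smoothing. The
filter is a 4th-order Butterworth at 6 Hz, applied forward–backward
(`filtfilt`) so it is zero-phase: idPhi's 5-second window is not shifted by
filter delay. Edges use odd (anti-symmetric) reflective padding, which
preserves linear yaw trends exactly; even (mirror) padding would bend a
steady rotation at the boundaries and bias idPhi on short trials. Sequences
shorter than the filter warm-up length, or sampled at ≤ 2× the cutoff, are
analyzed unfiltered with a logged warning rather than rejected.

## Memory score

The score is the Monte-Carlo percent rank of the response-to-target distance
among `n_reference = 1000` locations drawn uniformly over the arena disk
(`r = R√u`, θ uniform — uniform in area, respecting the circular boundary).
Ties are resolved in the navigator's favor: only reference points *strictly*
closer than the response count against the score, which makes a response
exactly at the target score exactly 100 regardless of the draw. Reference
points are redrawn per trial from a seed derived from (analysis seed,
participant, setup, block, trial), so results are reproducible but
uncorrelated across trials.

The estimator has an exact counterpart: the expected score is
`100·(1 − A∩/πR²)`, where `A∩` is the circle–circle intersection area of the
arena disk and the disk of radius ‖final − target‖ centered on the target
(lens formula, with the fully-inside and fully-covering regimes handled
separately). The Monte-Carlo score is an unbiased binomial estimate of this
quantity with SE = 100·√(p(1−p)/1000) ≈ 1.6 points at worst. Tests assert
agreement in distributional form — every random configuration within 4.5 SE
and no more than the chance-expected number beyond 3 SE — because with 200
independent configurations roughly one 3-SE exceedance is expected even from
a perfectly calibrated estimator; a 0.3-point floor covers binomial
discreteness where one reference point is worth 0.1 points.

## Scatter, efficiency metrics, maps

Scatter is the mean of the six pairwise distances among a block's four probe
responses, reported in meters by default. A divide-by-diameter option exists
because "relative distance" magnitudes reported for this class of task are
sometimes normalized by arena size; the formula itself is the literal
pairwise mean either way.

Path error divides the excess path length by the straight start→final
distance; when a navigator responds without moving (ideal length < 10⁻⁶ m)
the metric is undefined and recorded as missing, not infinity.

Surface coverage implements the bounding-box formula with *full* widths,
`π·|Δx|·|Δy|/(πR²)·100`, so a trajectory spanning the arena's bounding
square scores 400%. The formula is kept verbatim for comparability; a
`semi_axes=True` variant uses the inscribed ellipse (capping the same case
at 100%) for readers who prefer a true area fraction.

Presence maps mark a 20×20 grid cell visited if any sample of a trial falls
in it, then average the binary maps across trials. Sample-based visitation
is exact for this task's kinematics: at ≥ 60 Hz and ≤ 1.4 m/s a step moves
at most ~2.3 cm, far below the 0.38 m cell size, so no cell can be crossed
unseen. Final-location maps bin one response per trial on the same grid as
percentages, summing to 100 across cells.

## idPhi

Mean absolute first difference of the preprocessed yaw over samples whose
timestamp falls within 5 s of trial onset. The default unit is radians per
sample step, matching the plain `Σ|Δyaw|/n` definition; because that unit
depends on sampling rate, `per_second=True` multiplies by the rate to put
the 60 Hz and 90 Hz setups on a common rad/s scale. Trials shorter than the
window use all samples (flagged in the log); windows with fewer than two
samples yield a missing value.

## Trajectory distance (DTW)

Both trajectories are rotated about the arena center by the angle of their
own first sample, mapping the starts onto the zero-angle ray while
preserving radii. Using the measured start angle (rather than the designed
0/90/180/270° offset) lets the operation work on arbitrary data; for equal
start radii the two are equivalent. A start exactly at the center leaves the
rotation undefined and raises an error naming the trial.

The aligned position sequences are compared with classic full-boundary DTW:
squared-Euclidean local cost, steps {(1,0),(0,1),(1,1)}, unit weights. The
accumulated cost is normalized by the minimal admissible warping-path
length, `max(m, n)`, and square-rooted:
`trajectory_distance = √(cost/max(m,n))`. No resampling is applied before
warping — aligning paths regardless of their lengths is the point of DTW
here — and no band constraint is used. The dynamic program is JIT-compiled
with numba (pure-NumPy fallback); correctness is established against
exhaustive enumeration of all warping paths for every size up to 7×7.

## Synthetic navigators

The simulator reproduces the experiment's structure — not human
biomechanics — so that every metric and every group×setup contrast can be
exercised end to end without real recordings. Geometry and schedule follow
the task: R = 3.8 m; six blocks whose start locations sit on the boundary at
the six 60°-spaced radial axes; targets on a quadrant center axis (±45° or
±135° relative to the start) at a center distance uniform in [0.2, 0.8]·R;
3 learning + 4 probe trials per block with probe starts rotated by a
permutation of 0/90/180/270°; translation speed 1.4 m/s; capture radius
0.8 m; 60 Hz (stationary) / 90 Hz (mobile) sampling; scanning at the task's
50°/s rotation speed (reused for the mobile setup, which has no prescribed
analog for physical turning).

Agents move at constant speed with per-step heading dynamics — the simplest
model that spans the metrics' ranges:

- **direct**: optionally scan in place (`scan_duration` s, yaw sweeping at
  `scan_rate`, direction alternating each second), then walk toward
  `target + N(0, goal_noise_sigma²·I)` with per-step Gaussian heading
  perturbation. On learning trials the agent stops at the 0.8 m capture
  radius of the true target (the object is registered as found there); on
  probe trials it walks all the way to its goal estimate and the final
  sample is placed on it, so a noiseless agent scores a memory score of
  exactly 100.
- **random_search**: correlated random walk (per-step heading increments,
  s.d. ≥ 0.15 rad) with specular reflection at the wall, chosen over
  re-drawing so yaw stays continuous; ends at the capture radius (learning)
  or the time limit (probe).
- **path_replication**: egocentric replay — the block's last learning
  trajectory's displacement sequence, rotated by the probe rotation (the
  agent's reference frame rotates with the start), replayed from the new
  start. On a 180° probe the final location is therefore the point
  reflection of the learned final through the center, which scores below
  chance — the signature that dissociates route replay from allocentric
  navigation.

Every trial draws from its own RNG substream, emulating the disorientation
procedure's purpose of making consecutive trials independent; cohort
simulation derives all substreams from one seed and is byte-reproducible.
The default cohort (10 patient-like, 20 control-like agents) uses direct
navigation with a goal-noise × scan-duration interaction
(`DEFAULT_GROUP_EFFECTS`): higher goal noise and less scanning for the
patient-like group in the stationary setup, lower noise for everyone in the
mobile setup. These defaults produce the qualitative pattern of interest
(patients worst when stationary; both groups improve when mobile); they are
fixed conditions, not fitted quantities.

What the simulator does **not** model: head-bobbing/gait oscillations,
speed modulation, landmark-dependent heading corrections mid-path, learning
across blocks, or within-trial strategy switching. Passing tests therefore
demonstrate that the pipeline recovers known generative differences under
clean kinematics, not that it captures every property of human trajectories.

## Aggregation

Summaries follow trial → participant mean → group mean; SEM = SD/√n with n
the number of contributing participants. (A pooled-trials option exists for
diagnostics.) Scatter is computed per participant × setup × block across the
four probe responses and joins the summary as its own metric.
`export_model_table` emits one row per participant × setup × metric with
covariate columns, ready for an external mixed-model fit; an optional rule
log-transforms a metric whose skewness falls outside [−2, 2] or excess
kurtosis outside [−7, 7].

## Problem sizes

Validation suites use sizes chosen to make the statistics decisive at
interactive run times: exhaustive DTW checks at all sizes ≤ 7×7 (~10³
pairs), 200 random memory-score configurations against the closed form,
100 probe trials per goal-noise level, 50 seeded replication/direct pairs,
and one full 30-agent × 2-setup × 42-trial cohort for the interaction
pattern. The acceptance script scores 10,000 uniform responses with 1000
reference points each, giving a Monte-Carlo SE of ~0.3 points on the
chance-level mean.
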