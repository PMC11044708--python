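# Methods

## Posture classification

The classifier assumes a single-axis logger on the hind leg sampling at a
nominal 1 Hz, with the y-axis parallel to the leg: static gravity projects
≈ 1 g onto it while the sow stands and ≈ 0 g while she lies or sits. The
absolute value |y| is classified, so a logger mounted upside down (y ≈ −1 g
standing) behaves identically.

A sample is **lying** iff the smoothed |y| is strictly below the critical
lying value; a value exactly at the threshold counts as upright. Smoothing
is a moving median, which rejects short movement artefacts (scratching,
piglet contact, posture adjustments) without smearing step edges the way a
moving mean would.

Parameters:

| parameter | unit | default | rationale |
| --- | --- | --- | --- |
| `critical_value` | g | 0.75 | strict threshold: sows rarely lay the leg completely flat, so lying values sit well below standing but not at 0 |
| `window` | samples | 32 | ≈ 32 s at 1 Hz; longer than movement bursts, much shorter than real bouts |
| `smooth` | — | `"signal"` | median the |y| signal before thresholding; `"binary"` majority-votes the per-sample labels over the same window instead |
| `center` | — | `True` | centered window; a trailing window (`False`) is available for on-line use |
| `gap_tolerance` | s | 5 | inter-sample intervals above this are coverage gaps; must be explicit because loggers drop samples |

Numerical conventions, fixed and deliberate:

* The even default window is centered as 16 samples back / 15 forward; the
  median of an even count is the mean of the two central order statistics.
* Smoothing never crosses a coverage gap. Where the nominal window does
  not fit at a segment edge it truncates symmetrically to `[i−m, i+m]`,
  `m = min(i, n−1−i)`.
* Even-window caveat: on an ideal two-level signal the boundary sample
  sees an exact 16/16 split, whose median (midpoint of the two levels)
  lies below the threshold, so re-classifying a classifier's own 0/1
  re-encoding can shift each bout's boundary by one sample. With odd
  windows re-classification is exactly idempotent. This one-sample effect
  is irrelevant at bout scale but documented because the test suite pins
  it.

Bout extraction turns maximal lying runs into half-open intervals
`[first lying sample, first subsequent non-lying sample)`; at a segment
end the bout closes one nominal period after the last sample, so each
sample contributes exactly 1/rate seconds and total lying duration equals
(lying-sample count)/rate on nominally spaced data. Runs touching a
segment boundary are flagged `truncated_start`/`truncated_end`; bouts
never bridge gaps, mirroring the exclusion of faulty recordings rather
than imputation.

## Quarter-day summaries

Timestamps are timezone-naive barn wall-clock. Day 0 is the calendar date
of parturition (date difference, not 24-h offsets). Each day splits into
four 6-h quarters at 00/06/12/18, named late_night (00–06), morning
(06–12), afternoon (12–18) and early_night (18–24); the clock bounds of
the named quarters are configurable since only the names and the
18:00–24:00 / 00:00–06:00 night blocks are conventionally fixed. Lying
seconds are interval intersections (additive across quarters); bout counts
use start-attribution so a midnight-spanning bout is counted once.
Quarters with zero coverage produce no row; proportions divide by observed
coverage, not by 21600 s.

## Transitional sitting and agreement

Sows commonly pass through sitting when lying down or standing up, and the
leg orientation while sitting equals that while lying, so the sensor sees
one uninterrupted *rest* bout where video sees lying interrupted by
sitting. The reconciliation rule operates on the video ethogram: every
maximal chain of lying/sitting events with inter-event gaps ≤
`adjacency_tolerance` (default 1 s — one sample; video coding can leave
sub-second slivers) containing at least one lying event becomes a single
rest bout spanning the chain; sitting with no adjacent lying stays
upright. The merge can only reduce bout counts and only increase total
rest time.

Agreement is computed on a complete subjects × methods matrix (subjects
are sow × 24-h periods; windows with sensor coverage below 75 % are
dropped, a configurable fraction that keeps mostly-observed days). The
ICC form is fixed explicitly to McGraw–Wong **ICC(A,1)** — single
measure, absolute agreement, two-way random effects — because "two-way
random effects" alone does not pin the form; the consistency form
ICC(C,1) is available by flag. Estimates come from the two-way ANOVA mean
squares; confidence intervals use the standard F-based formulas
(Satterthwaite degrees of freedom for A,1, with the analytic MSE→0 limit
substituted when the error mean square vanishes). A matrix with zero
total variance raises a degenerate-result error instead of returning a
number. The implementation is validated in-suite against a definitional
brute-force ANOVA and against an independent published implementation.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:

* Per quarter, behaviour is an alternating upright/rest renewal process.
  Given targets (lying proportion p, rest-bout rate r per 6 h), episode
  durations are exponential with mean rest = p·21600/r and mean upright =
  (1−p)·21600/r, truncated at quarter boundaries; same-state episodes
  coalesce across boundaries so midnight-spanning rest is one ground-truth
  bout. Durations are floored (rest ≥ 60 s, upright ≥ 30 s by default —
  sows do not stand for seconds at a time; the floors also keep distinct
  rest bouts separated by more than the adjacency tolerance) and rounded
  to whole seconds to match 1 Hz sampling. The exponential choice is the
  simplest process matching the two targets; the duration distribution is
  not an empirical claim.
* Each rest episode is decomposed into lying pieces with transitional
  sitting: entry and exit sitting each with probability `sitting_prob`
  (default 0.3), interior interruptions Poisson with mean
  `sitting_prob`·duration/1800 s, sitting durations normal(25 s, 10 s)
  floored at 5 s. Sub-event durations always sum exactly to the episode,
  so merging transitional sitting reproduces the ground-truth rest table
  exactly.
* The sensor renders one leg angle per posture episode (standing 5° ± 3°
  from vertical, lying/sitting 85° ± 3°), y = cos(angle) + N(0, 0.05 g)
  per sample, plus N(0, 0.3 g) bursts for 5 s around each posture change
  (struggling to rise or flop down). cos is evaluated as sin(90°−a) so the
  noise-free extremes are exactly 1.0 and 0.0.
* Presets `crate_default` and `free_default` cover days −3…+27 relative to
  parturition with piecewise-linear day-courses: the crate preset peaks at
  ~5 bouts/6 h on day 0 and collapses after parturition; the free preset
  starts high, bottoms out after parturition and rises to ~8 bouts/6 h by
  day 20; both keep early-night lying proportion at 0.97 on all days. The
  presets are qualitative scenario fixtures, not reproductions of any
  field dataset.

What the simulator does **not** emulate — and therefore what passing tests
do not show about real data: lateral/sternal/ventral lying postures,
nursing and piglet interactions, free-standing sitting unrelated to
posture transitions, sensor drift or mounting slip, diurnal noise
structure, and any empirical bout-duration distribution. Agreement scores
on synthetic data (e.g. merged bout-count ICC near 1) are upper bounds
showing the machinery is consistent, not field validity claims.

## Problem sizes

The test and acceptance runs use desk-scale configurations chosen to make
the statistics stable: 100 random traces up to 10⁴ samples for the
smoother oracle, 12 simulated sow × 24-h subjects for the agreement study,
3–5 day scenarios for recovery checks, 100 simulated days for renewal
calibration, 1000 random matrices for ICC invariance, and 8 single-day
replicates per preset for realized preset behaviour.

## Known limitations

* The classifier is two-state by design; sitting is not detectable from a
  single hind-leg axis, which is exactly why the reconciliation rule
  exists.
* Duration exactness (lying seconds = sample count / rate) holds at
  nominal spacing; irregular sub-tolerance spacing preserves interval
  durations but not the count identity.
* The F-based ICC confidence interval is the classical approximation; for
  very small n it is wide and its clamping to [−1, 1] (and to contain the
  estimate) resolves only floating-point edge cases.
* Downstream inference (mixed models, splines over the day-course) is out
  of scope; the quarter summary table is the hand-off point.
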