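# Methods

## The measurement problem

International guidance for adolescents asks for 11,000 steps and 60 minutes
of moderate-to-vigorous physical activity (MVPA) per day. Averaging a
month's activity into one number hides the feature that matters for habit
formation: *regularity*. This package therefore analyses activity per day
and per subject, and tracks how often the daily targets are met over a
sliding week.

## Accelerometer epoch pipeline

Input is a per-second (configurable `epoch_s`) signal-vector-magnitude
series per subject. Modelling choices:

- **Cut points are configuration, not constants.** Published wrist
  cut-point sets differ by device, wear site and age group, and the
  appropriate set for children must be sourced from the calibration
  literature for the device at hand. The config ships placeholder values
  (`sedentary_max 0.5 / light_max 1.5 / moderate_max 3.0`, in SVM units)
  that demarcate the synthetic test streams; real analyses must supply
  literature values. All tests use explicit synthetic cut points.
- **Boundary convention:** intervals are half-open and lower-inclusive, so
  a magnitude exactly at a threshold takes the higher class. One convention
  had to be picked; it is documented and exercised by tests.
- **Bouts** are maximal runs of one intensity (moderate ∪ vigorous = MVPA).
  A recording gap terminates a run — a bout is a *continuous* episode — and
  runs below the class minimum (defaults: sedentary 60 s, MVPA 3 s, light
  3 s) are dropped, never merged across interruptions.
- **Daily windowing:** summaries count retained-bout seconds intersected
  with a half-open daytime window, 08:00–20:00 by default. Bouts straddling
  a boundary are clipped rather than wholly included/excluded, so
  within-window time is conserved.
- **Cohort tables** average within subject first, then across subjects, so
  subjects with more valid days do not dominate the cohort mean/SD.

## Tracker-day pipeline

Aggregated tracker days carry total steps and detected sessions with
duration and calories. Session intensity is recovered from the energy rate
(calories / duration): < 2 cal/min light, 2–3.5 moderate (both ends
inclusive), > 3.5 vigorous. The 11,000-step flag uses ≥ (the boundary
counts as achieved). Sessions are treated as disjoint within a day. Days
absent from the table are *missing*, not zero — they propagate as P(i) = 0
and are excluded from every average rather than imputed.

## Behavior clustering

Each subject-day's 5-feature vector (light/moderate/vigorous minutes,
steps, step-goal flag) is normalized and clustered with k-means
(scikit-learn, 10 restarts, fixed seed).

- **Normalization:** z-score by default (min-max selectable). The binary
  flag enters the distance raw as 0/1; only numerical features are scaled.
- **Choosing k:** the elbow rule is automated as the k maximizing the
  second difference of the within-cluster SSE curve, ties to the smallest
  k. This is a deliberate operationalisation of the usual eyeballed elbow;
  note its known behavior that three equally sized, equally spaced blobs
  can present their sharpest bend at k = 2 — the decision is driven by the
  SSE geometry, not by a preference for any k.
- **Ordering and values:** clusters are ranked by back-transformed centroid
  steps (tie-break: moderate + vigorous minutes; a steps+MVPA composite key
  is available). Rank j of k gets the achievement value j/(k−1), giving
  {0, 0.5, 1} for k = 3. Assignments and values are invariant to k-means'
  arbitrary label numbering.

## Consistency rate

For achievement degree R(i) ∈ [0, 1] and availability P(i) ∈ {0, 1},

CR(d) = Σ R(i)·P(i) / Σ P(i) over the n days ending at d (n = 7).

- The series starts on the n-th observation day (first complete window).
- An all-missing window is undefined (NaN), never 0 — zero means
  "consistently failed", which absent data cannot show.
- Implemented with rolling sums; the O(machine-eps) residue a running sum
  can leave is clamped to [0, 1]. Tests verify equivalence with direct
  per-window re-summation, monotone response to raising any single R, and
  missing-day neutrality (the denominator adjusts).
- Days-per-week conversion is rate × 7, rounded half-up to one decimal.
- Cohort trends average only subjects with a defined CR on each day;
  change is reported as end − start, labelled in percentage points for
  rate-scale targets (a "27 % increase" of this kind means 0.18 → 0.45).
- The least-active week-1 subgroup is defined per subject over program days
  1–7 (each subject's own first week; one school cohort typically starts
  together): week-1 achievement fraction < 50 % for the step target, or
  > 50 % of observed week-1 days in the lowest-ranked cluster for the
  cluster target.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, with
known ground truth:

- **Archetypes:** defaults are the three observed daily-behavior cluster
  centroids (steps 7,850 / 13,860 / 18,260; light 39/92/85, moderate
  5.3/16/57, vigorous 2.3/4/52 minutes) mixed with weights proportional to
  the observed cluster sizes (180:229:37). Default cohort: 24 subjects ×
  28 days.
- **Noise:** day-to-day variation is mean-preserving lognormal
  (cv default 0.1) — positive, right-skewed, multiplicative, which is how
  step counts and durations vary. cv = 0 degenerates to exact means.
- **Missingness:** independent Bernoulli per subject-day; missing days are
  absent from the records but present (flagged) in the ground truth.
- **Trend:** day-d means scale by 1 + t·(d−1)/(n_days−1), a linear ramp —
  the simplest shape for "gradual improvement". Note the implied last-week
  vs first-week ratio is slightly below 1 + t (window means of a ramp):
  ≈ 1.115 for t = 0.15 over 28 days.
- **Sessions:** one session per intensity class per day, duration equal to
  the true minutes, calorie rate at the band midpoint (1.5 / 2.75 / 4.5
  cal/min) — strictly interior, so the tracker pipeline recovers the true
  minutes exactly. 60 % of the day's steps are spread over sessions in
  proportion to duration, keeping session steps ≤ total steps.
- **Epoch streams** are built from an explicit (class, duration) plan with
  uniform magnitudes inside non-overlapping per-class bands; the true bout
  list is the run-length encoding of the plan.

What the generator does **not** emulate: within-day session-count
variability, autocorrelated day-to-day behavior, weather or weekday
effects, device-specific noise, or non-wear that truncates rather than
removes a day. Passing recovery tests therefore shows the pipeline is
correct under the assumed structure, not that real tracker data satisfy
that structure.

## Problem sizes and numerical choices

Oracle-equivalence tests run on streams up to 10^5 epochs and series of
10^3 days; parameter-recovery and trend-detection suites use 20 seeds of
the default 24 × 28 cohort. k-means uses 10 restarts with a fixed seed for
determinism. Floating-point comparisons against brute-force oracles use
rtol 1e-9 / atol 1e-12 (rolling-sum roundoff); all worked-example values
are exact.

## Known limitations

- Epoch cut points must be supplied by the user for real data; the
  defaults only suit the synthetic test streams.
- The elbow rule inspects only the SSE curve; cluster validity indices
  (silhouette, gap statistic) are out of scope.
- No inferential statistics on trends — the summaries are descriptive.
- Tracker session minutes are taken at face value; overlapping or
  double-counted vendor sessions are not detected.
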