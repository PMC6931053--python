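# pa-consistency

Analytics for adolescent physical-activity (PA) tracker data: how regularly
does a young person meet the international recommendations of **11,000 steps
and 60 minutes of moderate-to-vigorous PA (MVPA) per day** — and is that
regularity improving?

The package is aimed at researchers running school- or community-based PA
programs who collect (a) wrist accelerometer epoch streams for baseline
assessment and (b) daily aggregated consumer-tracker records (steps plus
detected activity sessions with duration and calories) across a multi-week
program.

## What it computes

**Bout-filtered accelerometry.** Per-second signal-vector-magnitude epochs
are labelled sedentary / light / moderate / vigorous by configurable cut
points (magnitudes at a threshold take the higher class). Bouts are maximal
runs of one intensity — moderate and vigorous merge to MVPA — and are kept
only if they last a minimum duration (60 s for sedentary, 3 s for MVPA).
Daily summaries accumulate retained-bout minutes inside a daytime window
(08:00–20:00).

**Daily behavior vectors and clustering.** Each tracker day becomes a
5-feature vector: light, moderate and vigorous minutes (session intensity
recovered from calories/min: < 2 light, 2–3.5 moderate, > 3.5 vigorous),
total steps, and a flag for ≥ 11,000 steps. Vectors are normalized and
clustered with k-means (k chosen by the elbow rule on the within-cluster
SSE). Clusters are ranked by activity (centroid steps) and cluster *j* of
*k* receives the achievement value *j/(k−1)* — so three clusters score
0, 0.5 and 1.

**Consistency rate.** For a daily target with achievement degree R(i) ∈
[0, 1] and data-availability indicator P(i) ∈ {0, 1}, the consistency rate
over the n-day window (n = 7) ending at day d is

    CR(d) = Σ_{i=d−n+1..d} R(i)·P(i) / Σ_{i=d−n+1..d} P(i)

Days without data are excluded from the average (never counted as
failures); an all-missing window is undefined rather than zero. Two targets
are built in: the binary step target (R = 1 iff steps ≥ 11,000) and the
graded cluster-value target. Cohort summaries report the group-mean CR per
day, its start / end / peak, the change in percentage points, the
least-active week-1 subgroup, and days-per-week conversions (0.48 → 3.4
days/week).

## Worked example

Simulate a 24-subject, 28-day cohort with a +30 % activity trend and 15 %
missing days, then run the full pipeline:

```bash
cat > spec.yaml <<EOF
n_subjects: 24
n_days: 28
missing_day_prob: 0.15
trend: 0.3
seed: 1
EOF
pa-consistency simulate --spec spec.yaml --out demo/sim
pa-consistency run --records demo/sim/daily_records.csv --out demo/run
```

which prints

```
wrote 1692 session rows for 24 subjects to demo/sim
k=3  subjects=24  vectors=564
steps: start 0.576  end 0.657  peak 0.657  change +0.081
cluster: start 0.351  end 0.354  peak 0.354  change +0.003
```

Read: the cohort met the 11,000-step target on 57.6 % of days in its first
week (CR is first defined on day 7) and on 65.7 % by the end — an
improvement of 8.1 percentage points, the injected trend showing through.
The fitted cluster table (`demo/run/cluster_summary.txt`) recovers the
three behavioral archetypes the simulator drew from:

```
 cluster  light_min  moderate_min  vigorous_min    steps  over_11k_majority   n  value
       0      38.92          5.31          2.28  7861.76              False 280    0.0
       1      91.66         15.87          3.98 13990.51               True 308    0.5
       2      85.76         56.68         52.03 18515.74               True  84    1.0
```

The run directory also contains per-subject and group consistency CSVs, the
cluster assignments, the echoed config, and a manifest with input hashes;
`pa-consistency report --run-dir demo/run` draws the group CR trend lines.

As a library, the same analysis is three calls:

```python
from pa_consistency import build_behavior_vectors, BehaviorClusterModel, \
    steps_achievement, consistency_rate

vectors = build_behavior_vectors(records_df)          # 5-feature days
results = BehaviorClusterModel(vectors, k="auto").fit()
print(results.summary())
cr = consistency_rate(steps_achievement(vectors[vectors.subject_id == "S01"]))
```

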