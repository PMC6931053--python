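"""End-to-end orchestration: records -> vectors -> clusters -> consistency.

A run reads the daily tracker records, builds behavior vectors, fits the
behavior clusters, computes both consistency targets (steps and cluster
value), identifies the least-active week-1 subgroups, and writes every
stage artifact plus a manifest of input hashes and the effective config to
the output directory.  Runs are deterministic given the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from pa_consistency.cluster import BehaviorClusterModel
from pa_consistency.config import RunConfig
from pa_consistency.consistency import (
    AchievementSeries,
    cluster_achievement,
    cohort_trend_summary,
    consistency_rate,
    identify_least_active,
    steps_achievement,
)
from pa_consistency.tracker import CalorieBands, build_behavior_vectors

log = logging.getLogger("pa_consistency")

__all__ = ["run_pipeline", "consistency_for_cohort"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def consistency_for_cohort(
    per_subject: dict[str, AchievementSeries], window_days: int = 7
) -> dict[str, pd.Series]:
    return {s: consistency_rate(series, window_days) for s, series in per_subject.items()}


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full analysis; returns the run manifest."""
    config.validate(require_records=True)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records_path = Path(config.records_path)
    records = pd.read_csv(records_path, parse_dates=["date"])
    needed = {"subject_id", "date", "total_steps"}
    if not needed <= set(records.columns):
        raise ValueError(f"records file missing column(s) {sorted(needed - set(records.columns))}")

    bands = CalorieBands(**config.calorie_bands)
    vectors = build_behavior_vectors(records, bands, config.step_goal)
    vectors.to_csv(out / "behavior_vectors.csv", index=False)
    log.info("built %d behavior vectors for %d subjects",
             len(vectors), vectors["subject_id"].nunique())

    model = BehaviorClusterModel(
        vectors,
        k=config.k,
        normalization=config.normalization,
        order_key=config.order_key,
        seed=config.seed,
        n_restarts=config.n_restarts,
    )
    results = model.fit()
    assignments = results.assignments()
    assignments.to_csv(out / "cluster_assignments.csv", index=False)
    results.centroid_table().to_csv(out / "cluster_centroids.csv", index=False)
    (out / "cluster_summary.txt").write_text(results.summary() + "\n")
    log.info("fitted k=%d clusters (SSE %.2f)", results.k, results.sse)

    # program span: shared calendar across the cohort
    span = pd.date_range(vectors["date"].min(), vectors["date"].max(), freq="D")
    steps_series: dict[str, AchievementSeries] = {}
    cluster_series: dict[str, AchievementSeries] = {}
    for subject, vecs in vectors.groupby("subject_id"):
        steps_series[str(subject)] = steps_achievement(vecs, config.step_goal, days=span)
        asg = assignments[assignments["subject_id"] == subject]
        cluster_series[str(subject)] = cluster_achievement(asg, days=span)

    rows = []
    summaries = {}
    for target, per_subject in (("steps", steps_series), ("cluster", cluster_series)):
        cr = consistency_for_cohort(per_subject, config.window_days)
        for subject, series in cr.items():
            for date, val in series.items():
                rows.append({"subject_id": subject, "date": date, "target": target, "cr": val})
        summaries[target] = cohort_trend_summary(cr)
    pd.DataFrame(rows).to_csv(out / "consistency.csv", index=False)

    group_rows = []
    for target, summ in summaries.items():
        for date, val in summ.mean_series.items():
            group_rows.append({"date": date, "target": target, "mean_cr": val})
    pd.DataFrame(group_rows).to_csv(out / "group_consistency.csv", index=False)

    least_active = {
        "steps": identify_least_active(
            steps_series, "steps", config.window_days, config.least_active_threshold
        ),
        "cluster": identify_least_active(
            cluster_series, "cluster", config.window_days, config.least_active_threshold
        ),
    }

    config.dump(out / "config.yaml")
    manifest = {
        "inputs": {records_path.name: _sha256(records_path)},
        "k": int(results.k),
        "n_vectors": int(len(vectors)),
        "n_subjects": int(vectors["subject_id"].nunique()),
        "least_active": least_active,
        "trend": {
            target: {
                "start": summ.start,
                "end": summ.end,
                "peak": summ.peak,
                "change": summ.change,
            }
            for target, summ in summaries.items()
        },
        "outputs": [
            "behavior_vectors.csv",
            "cluster_assignments.csv",
            "cluster_centroids.csv",
            "cluster_summary.txt",
            "consistency.csv",
            "group_consistency.csv",
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.info("run complete: %s", out / "manifest.json")
    return manifest
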