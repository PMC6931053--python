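"""Synthetic cohorts of tracker days and epoch streams with known truth.

The daily generator emulates the structure the analysis assumes: a cohort of
adolescents wearing a tracker for four weeks, each subject drawn from one of
a few behavioral archetypes (defaults follow the centroids of the three
daily behavior clusters observed in such cohorts: a less-active, an active
and a very-active profile).  Day-to-day variation is multiplicative
lognormal noise (mean-preserving; steps and durations are positive and
right-skewed), days go missing independently with a fixed probability
(device not worn / lost), and an optional linear trend scales the means from
day 1 to the last day to emulate gradual behavior change.

Every generated day carries one session per intensity class whose duration
equals the true minutes and whose calorie rate sits strictly inside the
class's calorie band, so the tracker-record pipeline recovers the true
minutes exactly.  The epoch-stream generator builds magnitude series from an
explicit segment plan and returns the exact bout structure alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pa_consistency.epochs import _RAW_TO_BOUT, Bout, EpochSeries

__all__ = [
    "ArchetypeSpec",
    "CohortSpec",
    "TABLE_ARCHETYPES",
    "TABLE_WEIGHTS",
    "generate_daily_cohort",
    "generate_epoch_stream",
]

#: calories/min emitted per class: midpoints of the calorie bands, safely
#: interior so classification is unambiguous
CLASS_CAL_RATE = {"light": 1.5, "moderate": 2.75, "vigorous": 4.5}

RECORD_COLUMNS = [
    "subject_id",
    "date",
    "total_steps",
    "session_idx",
    "duration_min",
    "steps",
    "calories",
]


@dataclass(frozen=True)
class ArchetypeSpec:
    """One behavioral archetype: mean daily activity and day-to-day noise."""

    name: str
    mean_steps: float
    mean_light: float
    mean_moderate: float
    mean_vigorous: float
    cv: float = 0.1

    def __post_init__(self) -> None:
        for fname in ("mean_steps", "mean_light", "mean_moderate", "mean_vigorous"):
            if getattr(self, fname) <= 0:
                raise ValueError(f"{fname} must be > 0 for archetype {self.name!r}")
        if not 0 <= self.cv < 1:
            raise ValueError(f"cv must lie in [0, 1) for archetype {self.name!r}")


#: default archetypes: centroids of the less-active / active / very-active
#: daily behavior clusters (steps; light/moderate/vigorous minutes)
TABLE_ARCHETYPES = [
    ArchetypeSpec("less active", mean_steps=7850, mean_light=39, mean_moderate=5.3, mean_vigorous=2.3),
    ArchetypeSpec("active", mean_steps=13860, mean_light=92, mean_moderate=16, mean_vigorous=4),
    ArchetypeSpec("very active", mean_steps=18260, mean_light=85, mean_moderate=57, mean_vigorous=52),
]
#: observed relative cluster sizes (180 / 229 / 37 of 446 subject-days)
TABLE_WEIGHTS = [180 / 446, 229 / 446, 37 / 446]


@dataclass
class CohortSpec:
    """Size, mixing weights, missingness, trend and seed of a synthetic cohort."""

    n_subjects: int = 24
    n_days: int = 28
    archetype_weights: list[float] = field(default_factory=lambda: list(TABLE_WEIGHTS))
    missing_day_prob: float = 0.0
    trend: float = 0.0
    seed: int = 0
    start_date: str = "2019-06-03"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_days < 7:
            raise ValueError("n_days must be >= 7")
        if not 0 <= self.missing_day_prob < 1:
            raise ValueError("missing_day_prob must lie in [0, 1)")
        if any(w < 0 for w in self.archetype_weights):
            raise ValueError("archetype_weights must be non-negative")
        if abs(sum(self.archetype_weights) - 1.0) > 1e-9:
            raise ValueError("archetype_weights must sum to 1")


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-1 lognormal multiplier with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def generate_daily_cohort(
    spec: CohortSpec, archetypes: list[ArchetypeSpec] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort's daily tracker records with ground truth.

    Returns ``(records, truth)``.  ``records`` is the long-format daily
    table (one row per session; missing days absent).  ``truth`` has one row
    per subject-day — including missing ones — with the subject's archetype,
    the true per-class minutes, true steps and the missing flag.

    With trend ``t``, day ``d`` means are scaled by ``1 + t*(d-1)/(n_days-1)``.
    """
    archetypes = list(TABLE_ARCHETYPES) if archetypes is None else archetypes
    names = [a.name for a in archetypes]
    if len(set(names)) != len(names):
        raise ValueError("archetype names must be unique")
    if len(spec.archetype_weights) != len(archetypes):
        raise ValueError("archetype_weights length must match archetypes")

    rng = np.random.default_rng(spec.seed)
    assignment = rng.choice(len(archetypes), size=spec.n_subjects, p=spec.archetype_weights)
    dates = pd.date_range(spec.start_date, periods=spec.n_days, freq="D")

    record_rows: list[dict] = []
    truth_rows: list[dict] = []
    for s in range(spec.n_subjects):
        subject = f"S{s + 1:02d}"
        arch = archetypes[assignment[s]]
        for d in range(spec.n_days):
            scale = 1.0
            if spec.n_days > 1:
                scale = 1.0 + spec.trend * d / (spec.n_days - 1)
            noise = _lognormal_factor(rng, arch.cv, size=4)
            steps = int(round(arch.mean_steps * scale * noise[0]))
            minutes = {
                "light": round(arch.mean_light * scale * noise[1], 3),
                "moderate": round(arch.mean_moderate * scale * noise[2], 3),
                "vigorous": round(arch.mean_vigorous * scale * noise[3], 3),
            }
            missing = bool(rng.random() < spec.missing_day_prob)
            truth_rows.append(
                {
                    "subject_id": subject,
                    "date": dates[d],
                    "archetype": arch.name,
                    "true_light_min": minutes["light"],
                    "true_moderate_min": minutes["moderate"],
                    "true_vigorous_min": minutes["vigorous"],
                    "true_steps": steps,
                    "missing": missing,
                }
            )
            if missing:
                continue
            # session steps: spread 60% of the total across sessions by
            # duration, so the session-steps-<=-total invariant always holds
            total_min = sum(minutes.values())
            for idx, cls in enumerate(("light", "moderate", "vigorous")):
                dur = minutes[cls]
                record_rows.append(
                    {
                        "subject_id": subject,
                        "date": dates[d],
                        "total_steps": steps,
                        "session_idx": idx,
                        "duration_min": dur,
                        "steps": int(0.6 * steps * dur / total_min) if total_min > 0 else 0,
                        "calories": round(dur * CLASS_CAL_RATE[cls], 4),
                    }
                )
    records = pd.DataFrame(record_rows, columns=RECORD_COLUMNS)
    truth = pd.DataFrame(truth_rows)
    return records, truth


def generate_epoch_stream(
    segments: list[tuple[str, float]],
    svm_bands: dict[str, tuple[float, float]],
    epoch_s: float = 1.0,
    subject_id: str = "S01",
    start: str | pd.Timestamp = "2019-06-03 08:00:00",
    seed: int = 0,
) -> tuple[EpochSeries, list[Bout]]:
    """Build an epoch magnitude stream from a segment plan, with true bouts.

    ``segments`` is an ordered list of ``(intensity class, duration_s)``;
    ``svm_bands`` maps each class to a non-overlapping ``(low, high)``
    magnitude band from which epoch values are drawn uniformly.  The true
    bout list is the run-length encoding of the plan at the bout-class level
    (adjacent moderate/vigorous segments merge into one MVPA run).
    """
    if not segments:
        raise ValueError("need at least one segment")
    bands = sorted(svm_bands.values())
    for (lo1, hi1), (lo2, hi2) in zip(bands, bands[1:]):
        if hi1 > lo2:
            raise ValueError("svm bands must be non-overlapping")
    for lo, hi in svm_bands.values():
        if not 0 <= lo < hi:
            raise ValueError("each svm band needs 0 <= low < high")
    for cls, dur in segments:
        if cls not in svm_bands:
            raise ValueError(f"no svm band for class {cls!r}")
        if dur <= 0 or (dur / epoch_s) % 1 > 1e-9:
            raise ValueError("segment durations must be positive multiples of epoch_s")

    rng = np.random.default_rng(seed)
    start = pd.Timestamp(start)
    svm_parts = []
    for cls, dur in segments:
        lo, hi = svm_bands[cls]
        svm_parts.append(rng.uniform(lo, hi, size=int(round(dur / epoch_s))))
    svm = np.concatenate(svm_parts)
    timestamps = start + pd.to_timedelta(np.arange(len(svm)) * epoch_s, unit="s")
    series = EpochSeries(subject_id=subject_id, timestamps=pd.DatetimeIndex(timestamps), svm=svm, epoch_s=epoch_s)

    # truth: merge adjacent segments that share a bout-level class
    bouts: list[Bout] = []
    offset = 0.0
    for cls, dur in segments:
        bcls = _RAW_TO_BOUT.get(cls, cls)
        if bouts and bouts[-1].intensity == bcls and abs(
            (bouts[-1].start - start).total_seconds() + bouts[-1].duration_s - offset
        ) < 1e-9:
            prev = bouts.pop()
            bouts.append(Bout(intensity=bcls, start=prev.start, duration_s=prev.duration_s + dur))
        else:
            bouts.append(
                Bout(intensity=bcls, start=start + pd.Timedelta(seconds=offset), duration_s=dur)
            )
        offset += dur
    return series, bouts
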