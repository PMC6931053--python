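"""Epoch-level accelerometry: intensity classification, bouts, daily summaries.

Wrist accelerometer recordings are assumed pre-processed into fixed-width
epochs (default 1 s) carrying a scalar signal vector magnitude (SVM).  Each
epoch is labelled sedentary / light / moderate / vigorous by cut points on
the SVM; moderate and vigorous roll up to MVPA for bout purposes.  A bout is
a maximal run of consecutive epochs at one (rolled-up) intensity; bouts
shorter than a class-specific minimum (60 s sedentary, 3 s MVPA by
convention) are discarded.  Daily summaries accumulate retained-bout time
inside a daytime window (08:00-20:00 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import time

import numpy as np
import pandas as pd

__all__ = [
    "RAW_CLASSES",
    "BOUT_CLASSES",
    "EpochSeries",
    "CutPointSet",
    "Bout",
    "DailyIntensitySummary",
    "classify_epochs",
    "detect_bouts",
    "summarize_day",
    "cohort_baseline_table",
]

RAW_CLASSES = ("sedentary", "light", "moderate", "vigorous")
#: classes at which bouts are detected; moderate and vigorous merge to MVPA
BOUT_CLASSES = ("sedentary", "light", "mvpa")

_RAW_TO_BOUT = {"sedentary": "sedentary", "light": "light", "moderate": "mvpa", "vigorous": "mvpa"}


@dataclass
class EpochSeries:
    """Per-subject epoch magnitudes on a fixed grid with explicit gaps.

    Timestamps must be strictly increasing and every spacing a positive
    multiple of ``epoch_s``; a spacing larger than ``epoch_s`` is a recording
    gap (absent epochs are never imputed).  ``labels``, when present, holds
    one raw intensity class per epoch.
    """

    subject_id: str
    timestamps: pd.DatetimeIndex
    svm: np.ndarray
    epoch_s: float = 1.0
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.svm = np.asarray(self.svm, dtype=float)
        if len(self.timestamps) != len(self.svm):
            raise ValueError("timestamps and svm must have equal length")
        if np.any(self.svm < 0):
            raise ValueError("svm must be non-negative")
        if len(self.timestamps) > 1:
            deltas = np.diff(self.timestamps.view("int64")) / 1e9
            if np.any(deltas <= 0):
                raise ValueError("timestamps must be strictly increasing")
            ratio = deltas / self.epoch_s
            if not np.allclose(ratio, np.round(ratio), atol=1e-9):
                raise ValueError("epoch spacing must be a multiple of epoch_s")

    def __len__(self) -> int:
        return len(self.svm)

    def gap_after(self) -> np.ndarray:
        """Boolean per epoch: True if a recording gap follows this epoch."""
        if len(self) <= 1:
            return np.zeros(len(self), dtype=bool)
        deltas = np.diff(self.timestamps.view("int64")) / 1e9
        out = np.zeros(len(self), dtype=bool)
        out[:-1] = deltas > self.epoch_s * (1 + 1e-9)
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"subject_id": self.subject_id, "timestamp": self.timestamps, "svm": self.svm}
        )
        if self.labels is not None:
            df["label"] = self.labels
        return df


@dataclass(frozen=True)
class CutPointSet:
    """SVM thresholds partitioning magnitudes into four intensity classes.

    Half-open, lower-bound-inclusive intervals: ``[0, sedentary_max)`` is
    sedentary, ``[sedentary_max, light_max)`` light, ``[light_max,
    moderate_max)`` moderate, ``[moderate_max, inf)`` vigorous — a magnitude
    exactly at a threshold takes the higher class.
    """

    sedentary_max: float
    light_max: float
    moderate_max: float

    def __post_init__(self) -> None:
        if not 0 < self.sedentary_max < self.light_max < self.moderate_max:
            raise ValueError("cut points must be strictly increasing and positive")

    @property
    def edges(self) -> np.ndarray:
        return np.array([self.sedentary_max, self.light_max, self.moderate_max])


@dataclass(frozen=True)
class Bout:
    """Maximal run of consecutive epochs at one bout-level intensity."""

    intensity: str
    start: pd.Timestamp
    duration_s: float

    def __post_init__(self) -> None:
        if self.intensity not in BOUT_CLASSES:
            raise ValueError(f"unknown bout class {self.intensity!r}")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")

    @property
    def end(self) -> pd.Timestamp:
        return self.start + pd.Timedelta(seconds=self.duration_s)


@dataclass
class DailyIntensitySummary:
    """Bout-filtered minutes per intensity class within the daytime window."""

    subject_id: str
    date: pd.Timestamp
    minutes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cls in BOUT_CLASSES:
            self.minutes.setdefault(cls, 0.0)


def classify_epochs(series: EpochSeries, cuts: CutPointSet) -> EpochSeries:
    """Assign each epoch one of the four raw intensity classes.

    Uses lower-bound-inclusive intervals (an SVM exactly at a cut point goes
    to the higher class).  Returns a new series carrying ``labels``.
    """
    idx = np.searchsorted(cuts.edges, series.svm, side="right")
    labels = np.array(RAW_CLASSES, dtype=object)[idx]
    return EpochSeries(
        subject_id=series.subject_id,
        timestamps=series.timestamps,
        svm=series.svm,
        epoch_s=series.epoch_s,
        labels=labels,
    )


def detect_bouts(
    series: EpochSeries, class_of_interest: str, min_duration_s: float
) -> list[Bout]:
    """Maximal runs of ``class_of_interest`` lasting at least ``min_duration_s``.

    ``class_of_interest`` is a bout-level class; ``"mvpa"`` matches moderate
    and vigorous epochs alike.  A recording gap terminates a run.  Runs
    shorter than the minimum are discarded, never merged with neighbours.
    """
    if class_of_interest not in BOUT_CLASSES:
        raise ValueError(f"unknown bout class {class_of_interest!r}; expected one of {BOUT_CLASSES}")
    if series.labels is None:
        raise ValueError("series must be classified first (run classify_epochs)")
    if min_duration_s <= 0 or (min_duration_s / series.epoch_s) % 1 > 1e-9:
        raise ValueError("min_duration_s must be a positive multiple of epoch_s")

    match = np.array([_RAW_TO_BOUT[l] == class_of_interest for l in series.labels])
    gap = series.gap_after()
    bouts: list[Bout] = []
    n = len(series)
    i = 0
    while i < n:
        if not match[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and match[j + 1] and not gap[j]:
            j += 1
        duration = (j - i + 1) * series.epoch_s
        if duration >= min_duration_s - 1e-9:
            bouts.append(
                Bout(
                    intensity=class_of_interest,
                    start=series.timestamps[i],
                    duration_s=duration,
                )
            )
        i = j + 1
    return bouts


def summarize_day(
    bouts: list[Bout],
    subject_id: str,
    date,
    window: tuple[time, time] = (time(8), time(20)),
) -> DailyIntensitySummary:
    """Accumulate retained-bout minutes per class within the daytime window.

    The window is half-open, [start, end); bouts straddling a boundary are
    clipped to it so that within-window time is conserved.
    """
    date = pd.Timestamp(date).normalize()
    win_start = date + pd.Timedelta(hours=window[0].hour, minutes=window[0].minute)
    win_end = date + pd.Timedelta(hours=window[1].hour, minutes=window[1].minute)
    minutes = {cls: 0.0 for cls in BOUT_CLASSES}
    for bout in bouts:
        lo = max(bout.start, win_start)
        hi = min(bout.end, win_end)
        overlap = (hi - lo).total_seconds()
        if overlap > 0:
            minutes[bout.intensity] += overlap / 60.0
    return DailyIntensitySummary(subject_id=subject_id, date=date, minutes=minutes)


def cohort_baseline_table(summaries: list[DailyIntensitySummary]) -> pd.DataFrame:
    """Cohort mean and SD of daily minutes per intensity class.

    Two-level averaging: each subject's days are averaged first, then mean
    and SD are taken across subjects, so subjects with more valid days do
    not dominate.
    """
    if not summaries:
        raise ValueError("need at least one daily summary")
    rows = [
        {"subject_id": s.subject_id, **{cls: s.minutes[cls] for cls in BOUT_CLASSES}}
        for s in summaries
    ]
    df = pd.DataFrame(rows)
    per_subject = df.groupby("subject_id")[list(BOUT_CLASSES)].mean()
    out = pd.DataFrame(
        {"mean": per_subject.mean(axis=0), "sd": per_subject.std(axis=0, ddof=1)}
    )
    out.index.name = "intensity"
    return out.fillna({"sd": 0.0})
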