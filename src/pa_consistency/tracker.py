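"""Daily aggregated tracker records -> intensity minutes and behavior vectors.

Consumer activity trackers expose each day as a total step count plus a list
of detected activity sessions (duration, steps, calories).  Session
intensity is recovered from the energy rate: sessions burning under 2
calories per minute are light, 2 to 3.5 (inclusive) moderate, and over 3.5
vigorous.  Each subject-day is then condensed into the 5-feature daily
behavior vector used for clustering: light / moderate / vigorous minutes,
total steps, and a flag for reaching the daily step goal (default 11,000).

Days absent from the record table are treated as "no data" downstream,
never as zero activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CalorieBands",
    "DailyTrackerRecord",
    "Session",
    "classify_session",
    "build_behavior_vector",
    "build_behavior_vectors",
    "mean_daily_steps",
]

VECTOR_COLUMNS = [
    "subject_id",
    "date",
    "light_min",
    "moderate_min",
    "vigorous_min",
    "steps",
    "over_11k",
]


@dataclass(frozen=True)
class CalorieBands:
    """Calories-per-minute thresholds separating intensity classes.

    Boundary convention: a rate exactly at ``light_max`` is moderate and a
    rate exactly at ``moderate_max`` is still moderate ("between 2 and 3.5"
    read as a closed interval; vigorous is strictly above).
    """

    light_max: float = 2.0
    moderate_max: float = 3.5

    def __post_init__(self) -> None:
        if not 0 < self.light_max < self.moderate_max:
            raise ValueError("need 0 < light_max < moderate_max")


@dataclass(frozen=True)
class Session:
    duration_min: float
    steps: int
    calories: float

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValueError("session duration must be positive")
        if self.calories < 0 or self.steps < 0:
            raise ValueError("session calories and steps must be non-negative")


@dataclass
class DailyTrackerRecord:
    subject_id: str
    date: pd.Timestamp
    total_steps: int
    sessions: list[Session]

    def __post_init__(self) -> None:
        if self.total_steps < 0:
            raise ValueError("total_steps must be non-negative")
        if sum(s.steps for s in self.sessions) > self.total_steps:
            raise ValueError("session steps exceed total_steps")


def classify_session(session: Session, bands: CalorieBands = CalorieBands()) -> str:
    """Intensity class of one session from its calories-per-minute rate."""
    rate = session.calories / session.duration_min
    if rate < bands.light_max:
        return "light"
    if rate <= bands.moderate_max:
        return "moderate"
    return "vigorous"


def build_behavior_vector(
    record: DailyTrackerRecord,
    bands: CalorieBands = CalorieBands(),
    step_goal: int = 11_000,
) -> dict:
    """The 5-feature daily behavior vector of one subject-day.

    Per-class minutes sum the durations of that day's sessions by class; a
    sessionless day has zero minutes.  The binary feature is True iff steps
    reached ``step_goal`` (at least; the boundary counts as achieved).
    """
    minutes = {"light": 0.0, "moderate": 0.0, "vigorous": 0.0}
    for session in record.sessions:
        minutes[classify_session(session, bands)] += session.duration_min
    return {
        "subject_id": record.subject_id,
        "date": pd.Timestamp(record.date),
        "light_min": minutes["light"],
        "moderate_min": minutes["moderate"],
        "vigorous_min": minutes["vigorous"],
        "steps": int(record.total_steps),
        "over_11k": record.total_steps >= step_goal,
    }


def records_from_frame(df: pd.DataFrame) -> list[DailyTrackerRecord]:
    """Parse the long-format daily records table (one row per session;
    session fields empty on sessionless day rows)."""
    records = []
    for (subject, date), grp in df.groupby(["subject_id", "date"], sort=True):
        total = int(grp["total_steps"].iloc[0])
        sessions = []
        with_sessions = grp[grp["duration_min"].notna()] if "duration_min" in grp else grp.iloc[0:0]
        for _, row in with_sessions.iterrows():
            sessions.append(
                Session(
                    duration_min=float(row["duration_min"]),
                    steps=int(row["steps"]),
                    calories=float(row["calories"]),
                )
            )
        records.append(
            DailyTrackerRecord(
                subject_id=str(subject),
                date=pd.Timestamp(date),
                total_steps=total,
                sessions=sessions,
            )
        )
    return records


def build_behavior_vectors(
    daily_records: pd.DataFrame,
    bands: CalorieBands = CalorieBands(),
    step_goal: int = 11_000,
) -> pd.DataFrame:
    """Behavior vectors for every subject-day in a long-format record table."""
    rows = [
        build_behavior_vector(rec, bands, step_goal)
        for rec in records_from_frame(daily_records)
    ]
    return pd.DataFrame(rows, columns=VECTOR_COLUMNS)


def mean_daily_steps(vectors: pd.DataFrame, group: list[str] | None = None) -> tuple[float, float]:
    """Group mean and SD of daily steps, averaging within subject first.

    ``group`` optionally restricts to a subject subset.  SD is across
    subject-level means (ddof=1; 0 for a single subject).
    """
    if group is not None:
        vectors = vectors[vectors["subject_id"].isin(group)]
    if vectors.empty:
        raise ValueError("no vectors to average")
    per_subject = vectors.groupby("subject_id")["steps"].mean()
    sd = float(per_subject.std(ddof=1)) if len(per_subject) > 1 else 0.0
    return float(per_subject.mean()), sd
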