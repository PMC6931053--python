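"""Sliding-window consistency rate of physical-activity target achievement.

The consistency rate CR(d) summarises how regularly a subject met a daily
target over the ``n`` days ending at day ``d`` (default 7, one week):

    CR(d) = sum_{i=d-n+1..d} R(i) * P(i)  /  sum_{i=d-n+1..d} P(i)

where ``R(i)`` in [0, 1] is the degree of target achievement on day ``i``
and ``P(i)`` in {0, 1} flags whether behavioral data were recorded that day
(a non-worn or lost device gives P = 0).  Days without data are excluded
from the average rather than counted as failures; a window with no recorded
data at all yields an undefined (NaN) value, never zero.

Two targets are supported: a binary step target (R = 1 iff the daily step
count reached the goal, default 11,000) and a graded cluster target where R
is the activity value of the day's behavior cluster (0, 0.5, 1 for k = 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "AchievementSeries",
    "TrendSummary",
    "steps_achievement",
    "cluster_achievement",
    "consistency_rate",
    "identify_least_active",
    "rate_to_days_per_week",
    "cohort_trend_summary",
]


@dataclass
class AchievementSeries:
    """Per-day achievement ``R`` and availability ``P`` for one subject.

    ``days`` is the complete calendar span of the observation period (program
    days), including days without data.  ``r`` holds NaN wherever ``p`` is 0.
    """

    subject: str
    days: pd.DatetimeIndex
    r: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.days = pd.DatetimeIndex(self.days)
        self.r = np.asarray(self.r, dtype=float)
        self.p = np.asarray(self.p, dtype=int)
        if not (len(self.days) == len(self.r) == len(self.p)):
            raise ValueError("days, r and p must have equal length")
        if not self.days.is_monotonic_increasing or self.days.has_duplicates:
            raise ValueError("days must be strictly increasing")
        observed = self.p == 1
        vals = self.r[observed]
        if len(vals) and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
            raise ValueError("R(i) must lie in [0, 1] on observed days")
        self.r = np.where(observed, self.r, np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.days, "R": self.r, "P": self.p})


def _full_day_index(dates: pd.Series, days: pd.DatetimeIndex | None) -> pd.DatetimeIndex:
    if days is not None:
        return pd.DatetimeIndex(days)
    dates = pd.to_datetime(dates)
    return pd.date_range(dates.min(), dates.max(), freq="D")


def steps_achievement(
    vectors: pd.DataFrame,
    step_goal: int = 11_000,
    days: pd.DatetimeIndex | None = None,
) -> AchievementSeries:
    """Binary step-target achievement series for one subject.

    ``vectors`` are that subject's daily behavior vectors (needs ``date`` and
    ``steps`` columns).  R(i) = 1 iff steps >= ``step_goal`` on an observed
    day; calendar days absent from ``vectors`` get P(i) = 0.  ``days``, if
    given, fixes the program span (e.g. to align subjects); by default it is
    the subject's own first-to-last observed day.
    """
    if vectors["subject_id"].nunique() > 1:
        raise ValueError("steps_achievement expects a single subject's vectors")
    subject = str(vectors["subject_id"].iloc[0])
    idx = _full_day_index(vectors["date"], days)
    per_day = vectors.set_index(pd.to_datetime(vectors["date"]))["steps"]
    if per_day.index.has_duplicates:
        raise ValueError("duplicate dates for subject")
    aligned = per_day.reindex(idx)
    p = (~aligned.isna()).to_numpy().astype(int)
    r = np.where(p == 1, (aligned.to_numpy() >= step_goal).astype(float), np.nan)
    return AchievementSeries(subject=subject, days=idx, r=r, p=p)


def cluster_achievement(
    assignments: pd.DataFrame,
    cluster_values: dict[int, float] | None = None,
    days: pd.DatetimeIndex | None = None,
) -> AchievementSeries:
    """Cluster-value achievement series for one subject.

    ``assignments`` needs ``date`` and either a ``value`` column (already in
    [0, 1]) or a ``cluster`` column resolved through ``cluster_values``.
    Every observed day must carry an assignment.
    """
    if assignments["subject_id"].nunique() > 1:
        raise ValueError("cluster_achievement expects a single subject's assignments")
    subject = str(assignments["subject_id"].iloc[0])
    if "value" in assignments.columns:
        vals = assignments["value"].astype(float)
    else:
        if cluster_values is None:
            raise ValueError("cluster_values required when assignments lack a 'value' column")
        unknown = set(assignments["cluster"]) - set(cluster_values)
        if unknown:
            raise KeyError(f"no cluster value for cluster(s) {sorted(unknown)}")
        vals = assignments["cluster"].map(cluster_values).astype(float)
    if vals.isna().any():
        raise ValueError("observed day lacking a cluster assignment value")
    idx = _full_day_index(assignments["date"], days)
    per_day = pd.Series(vals.to_numpy(), index=pd.to_datetime(assignments["date"]))
    aligned = per_day.reindex(idx)
    p = (~aligned.isna()).to_numpy().astype(int)
    return AchievementSeries(subject=subject, days=idx, r=aligned.to_numpy(), p=p)


def consistency_rate(series: AchievementSeries, n: int = 7) -> pd.Series:
    """Windowed consistency rate CR(d) for d = day n .. last day.

    Returns a Series indexed by calendar day, starting at the ``n``-th day of
    observation (the first day with a complete trailing window).  Windows
    containing no recorded data yield NaN (excluded, not zero).
    """
    if n < 1:
        raise ValueError("window length n must be >= 1")
    rp = pd.Series(np.where(series.p == 1, series.r, 0.0), index=series.days)
    pp = pd.Series(series.p.astype(float), index=series.days)
    num = rp.rolling(n).sum()
    den = pp.rolling(n).sum()
    # the running-sum kernel can leave O(eps) residue outside [0, 1]
    cr = (num / den.where(den > 0)).clip(0.0, 1.0)
    return cr.iloc[n - 1 :].rename("cr")


def rate_to_days_per_week(rate: float) -> float:
    """Convert an achievement fraction to days per week (rate x 7).

    Rounded half-up to one decimal, matching conventional reporting
    (0.48 -> 3.4, 0.59 -> 4.1).
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0, 1]")
    days = Decimal(str(float(rate))) * 7
    return float(days.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def identify_least_active(
    series_by_subject: dict[str, AchievementSeries],
    target_kind: str = "steps",
    week_days: int = 7,
    threshold: float = 0.5,
) -> list[str]:
    """Subjects who were least active in their first program week.

    For the ``steps`` target: subjects whose week-1 achievement fraction
    (mean R over observed days 1..7) is below ``threshold``.  For the
    ``cluster`` target: subjects who spent strictly more than ``threshold``
    of their observed week-1 days in the least-active cluster (R = 0).
    Subjects with no observed week-1 days are excluded.
    """
    if target_kind not in {"steps", "cluster"}:
        raise ValueError(f"unknown target_kind {target_kind!r}")
    out: list[str] = []
    for subject, series in series_by_subject.items():
        p = series.p[:week_days]
        r = series.r[:week_days]
        observed = p == 1
        if not observed.any():
            import warnings

            warnings.warn(f"subject {subject}: no observed days in week 1; excluded")
            continue
        if target_kind == "steps":
            if float(np.nanmean(r[observed])) < threshold:
                out.append(subject)
        else:
            frac_lowest = float(np.mean(r[observed] == 0.0))
            if frac_lowest > threshold:
                out.append(subject)
    return out


@dataclass
class TrendSummary:
    """Cohort-level consistency trend: per-day group mean and change.

    ``change`` is end minus start on the rate scale; ``change_points`` the
    same expressed in percentage points (the scale on which week-over-week
    improvements are conventionally reported).
    """

    mean_series: pd.Series
    start: float
    end: float
    peak: float
    change: float
    n_subjects: int
    change_points: float = field(init=False)

    def __post_init__(self) -> None:
        self.change_points = 100.0 * self.change

    def summary(self) -> str:
        lines = [
            "Consistency-rate trend summary",
            "------------------------------",
            f"subjects contributing : {self.n_subjects}",
            f"days with defined CR  : {int(self.mean_series.notna().sum())}",
            f"start (first defined) : {self.start:.3f}",
            f"end (last defined)    : {self.end:.3f}",
            f"peak                  : {self.peak:.3f}",
            f"change (end - start)  : {self.change:+.3f} "
            f"({self.change_points:+.1f} percentage points)",
        ]
        return "\n".join(lines)


def cohort_trend_summary(cr_by_subject: dict[str, pd.Series]) -> TrendSummary:
    """Average per-subject consistency series into a cohort trend.

    Each day's group mean uses only subjects with a defined CR that day (the
    missing-window exclusion propagates; nothing is imputed).  Start and end
    are the first and last days on which the group mean is defined; peak is
    the maximum over all defined days.
    """
    if not cr_by_subject:
        raise ValueError("need at least one subject series")
    frame = pd.DataFrame(cr_by_subject)
    mean_series = frame.mean(axis=1, skipna=True)
    defined = mean_series.dropna()
    if defined.empty:
        raise ValueError("no day has a defined consistency value")
    start = float(defined.iloc[0])
    end = float(defined.iloc[-1])
    peak = float(defined.max())
    return TrendSummary(
        mean_series=mean_series,
        start=start,
        end=end,
        peak=peak,
        change=end - start,
        n_subjects=frame.shape[1],
    )
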