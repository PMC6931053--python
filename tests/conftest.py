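import numpy as np
import pandas as pd
import pytest

from pa_consistency.consistency import AchievementSeries
from pa_consistency.epochs import EpochSeries


def make_epoch_series(svm, epoch_s=1.0, subject="S01", start="2019-06-03 08:00:00", drop=()):
    """EpochSeries from a magnitude array; indices in ``drop`` become gaps."""
    svm = np.asarray(svm, dtype=float)
    ts = pd.Timestamp(start) + pd.to_timedelta(np.arange(len(svm)) * epoch_s, unit="s")
    keep = np.ones(len(svm), dtype=bool)
    keep[list(drop)] = False
    return EpochSeries(
        subject_id=subject,
        timestamps=pd.DatetimeIndex(ts[keep]),
        svm=svm[keep],
        epoch_s=epoch_s,
    )


def make_achievement(r, p=None, subject="S01", start="2019-06-03"):
    r = np.asarray(r, dtype=float)
    p = np.ones(len(r), dtype=int) if p is None else np.asarray(p, dtype=int)
    days = pd.date_range(start, periods=len(r), freq="D")
    return AchievementSeries(subject=subject, days=days, r=r, p=p)


@pytest.fixture
def small_vectors():
    """Two subjects x 3 days of hand-written behavior vectors."""
    rows = []
    for sid, steps in (("A", [9000, 12000, 11000]), ("B", [7000, 7500, 8000])):
        for d, s in enumerate(steps):
            rows.append(
                {
                    "subject_id": sid,
                    "date": pd.Timestamp("2019-06-03") + pd.Timedelta(days=d),
                    "light_min": 30.0 + d,
                    "moderate_min": 10.0,
                    "vigorous_min": 2.0,
                    "steps": s,
                    "over_11k": s >= 11_000,
                }
            )
    return pd.DataFrame(rows)
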