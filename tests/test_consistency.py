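"""Consistency-rate statistic: worked examples, invariants, oracle equivalence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pa_consistency.consistency import (
    cluster_achievement,
    cohort_trend_summary,
    consistency_rate,
    identify_least_active,
    rate_to_days_per_week,
    steps_achievement,
)

from conftest import make_achievement


def brute_force_cr(r, p, n):
    """Direct per-window re-summation of the consistency definition."""
    out = []
    for d in range(n - 1, len(r)):
        num = sum(r[i] * p[i] for i in range(d - n + 1, d + 1) if p[i])
        den = sum(p[i] for i in range(d - n + 1, d + 1))
        out.append(num / den if den else np.nan)
    return np.array(out)


class TestWorkedExamples:
    def test_zero_achievement_week_is_zero(self):
        series = make_achievement([0] * 7)
        assert consistency_rate(series, 7).iloc[0] == 0.0

    def test_full_achievement_week_is_one(self):
        series = make_achievement([1] * 7)
        assert consistency_rate(series, 7).iloc[0] == 1.0

    def test_missing_day_adjusts_denominator(self):
        # R = (1,1,1,·,0,0,0) with the 4th day missing -> 3/6
        series = make_achievement([1, 1, 1, 0, 0, 0, 0], p=[1, 1, 1, 0, 1, 1, 1])
        assert consistency_rate(series, 7).iloc[0] == pytest.approx(0.5)

    def test_all_missing_window_is_undefined_not_zero(self):
        series = make_achievement([0] * 7, p=[0] * 7)
        assert np.isnan(consistency_rate(series, 7).iloc[0])

    def test_alternating_extreme_clusters_average_half(self):
        # a week alternating the value-0 and value-1 clusters, both phases
        phase_a = make_achievement([0, 1, 0, 1, 0, 1, 0])
        phase_b = make_achievement([1, 0, 1, 0, 1, 0, 1])
        crs = [consistency_rate(s, 7).iloc[0] for s in (phase_a, phase_b)]
        assert np.mean(crs) == pytest.approx(0.5)

    def test_series_starts_on_day_n(self):
        series = make_achievement([1] * 10)
        cr = consistency_rate(series, 7)
        assert len(cr) == 4
        assert cr.index[0] == series.days[6]


class TestDaysPerWeek:
    @pytest.mark.parametrize(
        "rate,expected",
        [(0.48, 3.4), (0.59, 4.1), (0.54, 3.8), (1.0, 7.0), (0.0, 0.0), (0.35, 2.5)],
    )
    def test_conversion(self, rate, expected):
        assert rate_to_days_per_week(rate) == expected

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            rate_to_days_per_week(1.2)


class TestAchievementSeries:
    def test_steps_achievement_boundary_and_missing(self):
        vecs = pd.DataFrame(
            {
                "subject_id": "A",
                "date": pd.to_datetime(["2019-06-03", "2019-06-05"]),
                "steps": [11_000, 10_999],
            }
        )
        series = steps_achievement(vecs, step_goal=11_000)
        assert list(series.p) == [1, 0, 1]
        assert series.r[0] == 1.0 and np.isnan(series.r[1]) and series.r[2] == 0.0

    def test_steps_achievement_matches_brute_force(self):
        rng = np.random.default_rng(11)
        days = pd.date_range("2019-06-03", periods=28)
        observed = rng.random(28) > 0.2
        steps = rng.integers(5_000, 20_000, size=28)
        vecs = pd.DataFrame(
            {"subject_id": "A", "date": days[observed], "steps": steps[observed]}
        )
        series = steps_achievement(vecs, 11_000, days=days)
        for i in range(28):
            if observed[i]:
                assert series.r[i] == float(steps[i] >= 11_000)
            else:
                assert series.p[i] == 0

    def test_cluster_achievement_values_and_errors(self):
        asg = pd.DataFrame(
            {
                "subject_id": "A",
                "date": pd.to_datetime(["2019-06-03", "2019-06-04"]),
                "cluster": [0, 2],
            }
        )
        series = cluster_achievement(asg, {0: 0.0, 1: 0.5, 2: 1.0})
        assert list(series.r) == [0.0, 1.0]
        with pytest.raises(KeyError):
            cluster_achievement(asg, {0: 0.0})


@st.composite
def masked_series(draw, max_len=40):
    length = draw(st.integers(7, max_len))
    r = draw(st.lists(st.floats(0, 1), min_size=length, max_size=length))
    p = draw(st.lists(st.integers(0, 1), min_size=length, max_size=length))
    return np.array(r), np.array(p)


class TestInvariants:
    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(masked_series())
    def test_equals_brute_force_and_bounded(self, rp):
        r, p = rp
        series = make_achievement(np.where(p == 1, r, 0), p=p)
        cr = consistency_rate(series, 7).to_numpy()
        expected = brute_force_cr(np.where(p == 1, r, 0), p, 7)
        np.testing.assert_allclose(cr, expected, rtol=1e-9, atol=1e-12, equal_nan=True)
        defined = cr[~np.isnan(cr)]
        assert ((defined >= 0) & (defined <= 1)).all()

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(masked_series(max_len=20), st.data())
    def test_monotone_response(self, rp, data):
        """Raising any single observed R never decreases any window's CR."""
        r, p = rp
        if p.sum() == 0:
            return
        idx = data.draw(st.sampled_from(np.flatnonzero(p == 1).tolist()))
        r = np.where(p == 1, r, 0)
        base = consistency_rate(make_achievement(r, p=p), 7).to_numpy()
        bumped = r.copy()
        bumped[idx] = 1.0
        high = consistency_rate(make_achievement(bumped, p=p), 7).to_numpy()
        mask = ~np.isnan(base)
        assert (high[mask] >= base[mask] - 1e-12).all()

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(masked_series(max_len=20), st.data())
    def test_missing_day_neutrality(self, rp, data):
        """Marking an observed day missing leaves CR equal to the mean of
        the remaining observed values in each window."""
        r, p = rp
        if p.sum() == 0:
            return
        idx = data.draw(st.sampled_from(np.flatnonzero(p == 1).tolist()))
        r = np.where(p == 1, r, 0)
        p2 = p.copy()
        p2[idx] = 0
        cr2 = consistency_rate(make_achievement(np.where(p2 == 1, r, 0), p=p2), 7).to_numpy()
        expected = brute_force_cr(np.where(p2 == 1, r, 0), p2, 7)
        np.testing.assert_allclose(cr2, expected, rtol=1e-9, atol=1e-12, equal_nan=True)

    def test_window_shift_identity_full_data(self):
        rng = np.random.default_rng(5)
        r = rng.random(60)
        cr = consistency_rate(make_achievement(r), 7).to_numpy()
        for d in range(len(cr) - 1):
            shift = (r[d + 7] - r[d]) / 7
            assert cr[d + 1] - cr[d] == pytest.approx(shift, abs=1e-12)

    def test_sliding_equals_resummation_long_series(self):
        rng = np.random.default_rng(7)
        r = rng.random(1000)
        p = (rng.random(1000) > 0.15).astype(int)
        r = np.where(p == 1, r, 0)
        cr = consistency_rate(make_achievement(r, p=p), 7).to_numpy()
        np.testing.assert_allclose(cr, brute_force_cr(r, p, 7), rtol=1e-9, atol=1e-12, equal_nan=True)


class TestLeastActive:
    def test_steps_target_threshold(self):
        low = make_achievement([1, 1, 1, 0, 0, 0, 0], subject="low")  # 3/7 = 43%
        high = make_achievement([1, 1, 1, 1, 0, 0, 0], subject="high")  # 4/7 = 57%
        out = identify_least_active({"low": low, "high": high}, "steps")
        assert out == ["low"]

    def test_cluster_target_majority_in_lowest(self):
        mostly_low = make_achievement([0, 0, 0, 0, 0.5, 1, 1], subject="a")  # 4/7 in lowest
        split = make_achievement([0, 0, 0, 1, 1, 1, 0.5], subject="b")  # 3/7
        out = identify_least_active({"a": mostly_low, "b": split}, "cluster")
        assert out == ["a"]

    def test_subject_without_week1_data_excluded(self):
        empty = make_achievement([0] * 7, p=[0] * 7, subject="e")
        with pytest.warns(UserWarning):
            out = identify_least_active({"e": empty}, "steps")
        assert out == []


class TestTrendSummary:
    def test_start_end_peak_change(self):
        days = pd.date_range("2019-06-09", periods=4)
        s1 = pd.Series([0.18, 0.30, 0.51, 0.45], index=days)
        summ = cohort_trend_summary({"A": s1})
        assert summ.start == pytest.approx(0.18)
        assert summ.end == pytest.approx(0.45)
        assert summ.peak == pytest.approx(0.51)
        assert summ.change_points == pytest.approx(27.0)
        assert "+27.0 percentage points" in summ.summary()

    def test_constant_series_change_zero(self):
        days = pd.date_range("2019-06-09", periods=5)
        summ = cohort_trend_summary({"A": pd.Series(0.4, index=days)})
        assert summ.change == 0.0 and summ.peak == summ.start

    def test_group_mean_skips_undefined_subjects(self):
        days = pd.date_range("2019-06-09", periods=3)
        a = pd.Series([0.2, np.nan, 0.6], index=days)
        b = pd.Series([0.4, 0.5, np.nan], index=days)
        summ = cohort_trend_summary({"A": a, "B": b})
        np.testing.assert_allclose(summ.mean_series.to_numpy(), [0.3, 0.5, 0.6])
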