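import math
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from buzzpam import metrics


class TestBuzzPerHour:
    def test_formula(self):
        assert metrics.buzz_per_hour(6, 12) == 30.0

    def test_zero_count(self):
        assert metrics.buzz_per_hour(0, 12) == 0.0

    def test_hand_arithmetic(self):
        # 13 buzzes over a 6-h window with 12 recorded min/h
        assert metrics.buzz_per_hour(13, 72) == pytest.approx(13 / 72 * 60)

    def test_zero_recorded_is_missing(self):
        assert math.isnan(metrics.buzz_per_hour(5, 0))
        assert math.isnan(metrics.buzz_per_hour(5, -1))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            metrics.buzz_per_hour(-1, 12)

    @given(count=st.integers(0, 1000), minutes=st.floats(0.1, 60))
    def test_linear_in_count(self, count, minutes):
        one = metrics.buzz_per_hour(1, minutes)
        assert metrics.buzz_per_hour(count, minutes) == pytest.approx(count * one)

    @given(count=st.integers(1, 1000), minutes=st.floats(0.2, 60))
    def test_halving_minutes_doubles_rate(self, count, minutes):
        assert metrics.buzz_per_hour(count, minutes / 2) == pytest.approx(
            2 * metrics.buzz_per_hour(count, minutes)
        )


class TestStandardizeCounts:
    @pytest.mark.parametrize(
        "total,n,expected", [(40, 4, 10.0), (0, 6, 0.0), (17, 2, 8.5)]
    )
    def test_examples(self, total, n, expected):
        row = {
            "n_replicates": n,
            "total_abundance": total,
            "flying_abundance": 0,
        }
        assert metrics.standardize_counts(row)[0] == expected

    def test_flying_analog(self):
        row = {"n_replicates": 4, "total_abundance": 40, "flying_abundance": 30}
        assert metrics.standardize_counts(row) == (10.0, 7.5)

    def test_zero_replicates(self):
        with pytest.raises(ValueError):
            metrics.standardize_counts(
                {"n_replicates": 0, "total_abundance": 1, "flying_abundance": 0}
            )

    def test_flying_above_total_rejected(self):
        with pytest.raises(ValueError):
            metrics.standardize_counts(
                {"n_replicates": 1, "total_abundance": 1, "flying_abundance": 2}
            )


def activity_frame(rows):
    return pd.DataFrame(
        rows,
        columns=metrics.ACTIVITY_COLUMNS,
    )


class TestHourlySiteMean:
    def test_four_devices(self):
        hour = datetime(2023, 4, 22, 10)
        rows = [
            (f"d{i}", "A", hour, 0, 12.0, v) for i, v in enumerate([10, 20, 30, 40])
        ]
        assert metrics.hourly_site_mean(activity_frame(rows), "A", 10) == 25.0

    def test_single_device_identity(self):
        rows = [("d0", "A", datetime(2023, 4, 22, 10), 0, 12.0, 17.5)]
        assert metrics.hourly_site_mean(activity_frame(rows), "A", 10) == 17.5

    def test_missing_rows_skipped(self):
        hour = datetime(2023, 4, 22, 10)
        rows = [
            ("d0", "A", hour, 0, 12.0, 10.0),
            ("d1", "A", hour, 0, 0.0, math.nan),
        ]
        assert metrics.hourly_site_mean(activity_frame(rows), "A", 10) == 10.0

    def test_no_rows_is_nan(self):
        assert math.isnan(metrics.hourly_site_mean(activity_frame([]), "A", 10))

    def test_matches_brute_force_groupby(self, rng):
        rows = []
        for i in range(300):
            rows.append(
                (
                    f"d{rng.integers(4)}",
                    rng.choice(["A", "B"]),
                    datetime(2023, 4, 22) + timedelta(hours=int(rng.integers(72))),
                    0,
                    12.0,
                    float(rng.uniform(0, 50)),
                )
            )
        df = activity_frame(rows)
        for site in ("A", "B"):
            for hod in range(24):
                expected = [
                    v
                    for _, s, h, _, _, v in rows
                    if s == site and h.hour == hod
                ]
                got = metrics.hourly_site_mean(df, site, hod)
                if expected:
                    assert got == pytest.approx(np.mean(expected))
                else:
                    assert math.isnan(got)


def brute_force_bin(t, edges):
    labels = metrics.temperature_bin_labels(edges)
    for i, e in enumerate(edges):
        if t < e:
            return labels[i]
    return labels[-1]


class TestTemperatureBins:
    def test_examples(self):
        assert metrics.assign_temperature_bin(22.0) == "20-25"
        assert metrics.assign_temperature_bin(20.0) == "20-25"  # left-closed
        assert metrics.assign_temperature_bin(31.0) == "30+"
        assert metrics.assign_temperature_bin(10.0) == "<15"

    def test_bad_edges(self):
        with pytest.raises(ValueError):
            metrics.assign_temperature_bin(20.0, edges=[20, 15])

    def test_matches_linear_scan_1000_random(self, rng):
        edges = (15.0, 20.0, 25.0, 30.0)
        for t in rng.uniform(-5, 45, size=1000):
            assert metrics.assign_temperature_bin(float(t), edges) == brute_force_bin(
                float(t), edges
            )

    def test_bin_by_temperature_peaked_activity(self, rng):
        # activity responds to temperature through a bump at 22.5 degC
        rows, trows = [], []
        for i in range(800):
            t = float(rng.uniform(12, 34))
            rate = 30 * math.exp(-((t - 22.5) ** 2) / (2 * 4.0**2))
            hour = datetime(2023, 4, 22) + timedelta(hours=i)
            bph = float(rng.poisson(rate * 0.2) / 12 * 60)
            rows.append(("d0", "A", hour, 0, 12.0, bph))
            trows.append({"site_id": "A", "hour_start": hour, "temperature": t})
        out = metrics.bin_by_temperature(
            activity_frame(rows), pd.DataFrame(trows)
        ).set_index("temp_bin")
        m = out["mean_buzz_per_hour"]
        assert m["20-25"] > m["25-30"] > m["15-20"]
        assert (out.loc[["15-20", "20-25", "25-30"], "se"] > 0).all()

    def test_missing_temperature_warns(self):
        hour = datetime(2023, 4, 22, 10)
        act = activity_frame([("d0", "A", hour, 2, 12.0, 10.0)])
        temps = pd.DataFrame(
            [{"site_id": "A", "hour_start": hour + timedelta(hours=5), "temperature": 20.0}]
        )
        with pytest.warns(UserWarning, match="lack a temperature"):
            out = metrics.bin_by_temperature(act, temps)
        assert out["n"].sum() == 0

    def test_se_uses_n_minus_1(self):
        hours = [datetime(2023, 4, 22, 10) + timedelta(hours=i) for i in range(3)]
        vals = [10.0, 20.0, 30.0]
        act = activity_frame(
            [("d0", "A", h, 0, 12.0, v) for h, v in zip(hours, vals)]
        )
        temps = pd.DataFrame(
            [{"site_id": "A", "hour_start": h, "temperature": 22.0} for h in hours]
        )
        out = metrics.bin_by_temperature(act, temps).set_index("temp_bin")
        assert out.loc["20-25", "se"] == pytest.approx(np.std(vals, ddof=1) / np.sqrt(3))


class TestPearson:
    def test_perfect_positive(self):
        assert metrics.pearson_r([1, 2, 3], [2, 4, 6]).r == pytest.approx(1.0, abs=1e-12)

    def test_perfect_negative(self):
        assert metrics.pearson_r([1, 2, 3], [3, 2, 1]).r == pytest.approx(-1.0, abs=1e-12)

    def test_hand_computed(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([2.0, 4, 5, 4])
        dx, dy = x - x.mean(), y - y.mean()
        expected = (dx * dy).sum() / math.sqrt((dx**2).sum() * (dy**2).sum())
        res = metrics.pearson_r(x, y)
        assert res.r == pytest.approx(expected)
        assert res.n == 4

    def test_matches_scipy(self, rng):
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        res = metrics.pearson_r(x, y)
        ref = stats.pearsonr(x, y)
        assert res.r == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_vector_error(self):
        with pytest.raises(ValueError):
            metrics.pearson_r([1, 1, 1], [1, 2, 3])

    def test_too_few(self):
        with pytest.raises(ValueError):
            metrics.pearson_r([1, 2], [3, 4])

    @given(
        a=st.floats(0.1, 10),
        b=st.floats(-5, 5),
        c=st.floats(0.1, 10),
        d=st.floats(-5, 5),
        seed=st.integers(0, 100),
    )
    @settings(max_examples=40, deadline=None)
    def test_affine_invariance(self, a, b, c, d, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        r0 = metrics.pearson_r(x, y).r
        r1 = metrics.pearson_r(a * x + b, c * y + d).r
        assert abs(r0) <= 1.0
        assert r1 == pytest.approx(r0, abs=1e-9)


class TestCompareDaytimeVs24h:
    def _series(self, value_fn, days=14):
        rows = []
        for d in range(days):
            for h in range(24):
                hour = datetime(2023, 4, 17) + timedelta(days=d, hours=h)
                rows.append(("d0", "A", hour, 0, 12.0, value_fn(h)))
        return activity_frame(rows)

    def test_night_only_activity(self):
        out = metrics.compare_daytime_vs_24h(
            self._series(lambda h: 0.0 if 6 <= h < 21 else 5.0), "A"
        )
        assert (out["daytime_mean"] == 0).all()
        assert (out["full_day_mean"] > 0).all()

    def test_uniform_activity_equal_means(self):
        out = metrics.compare_daytime_vs_24h(self._series(lambda h: 7.0), "A")
        assert out["daytime_mean"].tolist() == pytest.approx(out["full_day_mean"].tolist())

    def test_diurnal_excess(self):
        out = metrics.compare_daytime_vs_24h(
            self._series(lambda h: 12.0 if 6 <= h < 21 else 10.0), "A"
        )
        assert (out["daytime_mean"] > out["full_day_mean"]).all()

    def test_weeks_keyed_iso(self):
        out = metrics.compare_daytime_vs_24h(self._series(lambda h: 1.0), "A")
        assert out["iso_week"].str.match(r"\d{4}-W\d{2}").all()
        assert len(out) == 2  # 14 days starting Monday 2023-04-17 = 2 ISO weeks

    def test_empty(self):
        out = metrics.compare_daytime_vs_24h(activity_frame([]), "A")
        assert out.empty


class TestAggregateHourly:
    def test_basic(self):
        summary = pd.DataFrame(
            [
                {
                    "device_id": "d0",
                    "site_id": "A",
                    "start_time": "2023-04-22 10:00:00",
                    "duration_s": 720.0,
                    "count": 6,
                },
                {
                    "device_id": "d0",
                    "site_id": "A",
                    "start_time": "2023-04-22 10:30:00",
                    "duration_s": 720.0,
                    "count": 2,
                },
            ]
        )
        out = metrics.aggregate_hourly(summary)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["buzz_count"] == 8
        assert row["recorded_min"] == 24.0
        assert row["buzz_per_hour"] == pytest.approx(8 / 24 * 60)
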