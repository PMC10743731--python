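"""Activity metrics derived from buzz counts.

The central quantity is buzz/h: buzzes counted in a time frame divided
by the minutes actually recorded in that frame and scaled to an hour.
Counts from traditional surveys are standardized per replicate before
being correlated with acoustic activity.
"""

from __future__ import annotations

import math
import warnings
from datetime import time
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ACTIVITY_COLUMNS",
    "SURVEY_COLUMNS",
    "PearsonResult",
    "buzz_per_hour",
    "standardize_counts",
    "aggregate_hourly",
    "hourly_site_mean",
    "assign_temperature_bin",
    "temperature_bin_labels",
    "bin_by_temperature",
    "pearson_r",
    "compare_daytime_vs_24h",
]

ACTIVITY_COLUMNS = [
    "device_id",
    "site_id",
    "hour_start",
    "buzz_count",
    "recorded_min",
    "buzz_per_hour",
]
SURVEY_COLUMNS = [
    "site_id",
    "period",
    "method",
    "n_replicates",
    "total_abundance",
    "flying_abundance",
]

DEFAULT_TEMP_EDGES = (15.0, 20.0, 25.0, 30.0)
DAYTIME = (time(6), time(21))


def buzz_per_hour(count: float, recorded_minutes: float) -> float:
    """Buzz events per hour of equivalent continuous recording.

    ``count / recorded_minutes * 60``. A non-positive recorded time is a
    missing value (NaN), never zero.
    """
    if count < 0:
        raise ValueError("count must be non-negative")
    if recorded_minutes <= 0:
        return math.nan
    return count / recorded_minutes * 60.0


def standardize_counts(row: dict | pd.Series) -> tuple[float, float]:
    """Per-replicate abundances ``(total, flying_only)`` for one survey row."""
    n = int(row["n_replicates"])
    if n < 1:
        raise ValueError("n_replicates must be >= 1")
    total = float(row["total_abundance"])
    flying = float(row["flying_abundance"])
    if total < 0 or flying < 0 or flying > total:
        raise ValueError("abundances must satisfy 0 <= flying <= total")
    return total / n, flying / n


def aggregate_hourly(summary: pd.DataFrame) -> pd.DataFrame:
    """Build an hourly activity table from per-recording detection summaries.

    ``summary`` needs columns ``device_id, site_id, start_time,
    duration_s, count``; each recording is attributed to the clock hour
    containing its start. Returns one row per (device, site, hour) with
    buzz_count, recorded_min and buzz_per_hour.
    """
    df = summary.copy()
    df["start_time"] = pd.to_datetime(df["start_time"])
    df["hour_start"] = df["start_time"].dt.floor("h")
    grouped = (
        df.groupby(["device_id", "site_id", "hour_start"], as_index=False)
        .agg(buzz_count=("count", "sum"), recorded_s=("duration_s", "sum"))
    )
    grouped["recorded_min"] = grouped["recorded_s"] / 60.0
    grouped["buzz_per_hour"] = [
        buzz_per_hour(c, m)
        for c, m in zip(grouped["buzz_count"], grouped["recorded_min"])
    ]
    return grouped[ACTIVITY_COLUMNS]


def hourly_site_mean(
    activity: pd.DataFrame, site_id: str, hour_of_day: int
) -> float:
    """Mean buzz/h across devices (and days) at one site and clock hour.

    Missing rows (NaN buzz/h) are skipped; returns NaN when no valid
    rows exist.
    """
    df = activity[activity["site_id"] == site_id]
    hours = pd.to_datetime(df["hour_start"]).dt.hour
    vals = df.loc[hours == hour_of_day, "buzz_per_hour"].dropna()
    if vals.empty:
        return math.nan
    return float(vals.mean())


def temperature_bin_labels(edges: Sequence[float] = DEFAULT_TEMP_EDGES) -> list[str]:
    labels = [f"<{edges[0]:g}"]
    labels += [f"{lo:g}-{hi:g}" for lo, hi in zip(edges[:-1], edges[1:])]
    labels.append(f"{edges[-1]:g}+")
    return labels


def assign_temperature_bin(
    temperature: float, edges: Sequence[float] = DEFAULT_TEMP_EDGES
) -> str:
    """Left-closed right-open bin label for a temperature.

    A temperature equal to a shared edge belongs to the upper bin
    (e.g. 20 degC -> "20-25"); the last bin is open above.
    """
    edges = list(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing")
    idx = int(np.digitize([temperature], edges, right=False)[0])
    return temperature_bin_labels(edges)[idx]


def bin_by_temperature(
    activity: pd.DataFrame,
    temps: pd.DataFrame,
    edges: Sequence[float] = DEFAULT_TEMP_EDGES,
) -> pd.DataFrame:
    """Mean buzz/h (+/- SE) per temperature range.

    ``temps`` has columns ``site_id, hour_start, temperature`` (the
    hour's maximum logger reading where available). Hourly activity rows
    are joined on (site_id, hour_start); rows without a temperature are
    excluded with a warning. SE uses the n-1 standard deviation.
    """
    act = activity.copy()
    act["hour_start"] = pd.to_datetime(act["hour_start"])
    tmp = temps.copy()
    tmp["hour_start"] = pd.to_datetime(tmp["hour_start"])
    merged = act.merge(tmp, on=["site_id", "hour_start"], how="left")
    n_missing = merged["temperature"].isna().sum()
    if n_missing:
        warnings.warn(
            f"{n_missing} activity rows lack a temperature and were excluded",
            stacklevel=2,
        )
        merged = merged.dropna(subset=["temperature"])
    merged = merged.dropna(subset=["buzz_per_hour"])
    merged["temp_bin"] = [
        assign_temperature_bin(t, edges) for t in merged["temperature"]
    ]

    rows = []
    for label in temperature_bin_labels(edges):
        vals = merged.loc[merged["temp_bin"] == label, "buzz_per_hour"].to_numpy()
        n = len(vals)
        mean = float(vals.mean()) if n else math.nan
        se = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
        rows.append({"temp_bin": label, "mean_buzz_per_hour": mean, "se": se, "n": n})
    return pd.DataFrame(rows)


class PearsonResult(NamedTuple):
    r: float
    p: float
    n: int


def pearson_r(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Sample Pearson correlation with a two-sided t-test p-value.

    Product-moment formula; significance from ``t = r sqrt((n-2)/(1-r^2))``
    with n-2 degrees of freedom. Raises ``ValueError`` for n < 3 or a
    constant vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = math.sqrt(float(dx @ dx))
    sy = math.sqrt(float(dy @ dy))
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(dx @ dy) / (sx * sy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return PearsonResult(r=r, p=p, n=n)


def compare_daytime_vs_24h(
    activity: pd.DataFrame,
    site_id: str,
    daytime: tuple[time, time] = DAYTIME,
) -> pd.DataFrame:
    """Weekly mean buzz/h under a daytime-only and a 24 h window.

    Weeks are keyed by ISO year/week of the hour start. Empty weeks are
    absent from the output.
    """
    df = activity[activity["site_id"] == site_id].copy()
    df["hour_start"] = pd.to_datetime(df["hour_start"])
    df = df.dropna(subset=["buzz_per_hour"])
    if df.empty:
        return pd.DataFrame(columns=["iso_week", "daytime_mean", "full_day_mean"])
    iso = df["hour_start"].dt.isocalendar()
    df["iso_week"] = iso["year"].astype(str) + "-W" + iso["week"].astype(str).str.zfill(2)
    tod = df["hour_start"].dt.time
    is_day = (tod >= daytime[0]) & (tod < daytime[1])

    rows = []
    for week, grp in df.groupby("iso_week"):
        day_vals = grp.loc[is_day.loc[grp.index], "buzz_per_hour"]
        rows.append(
            {
                "iso_week": week,
                "daytime_mean": float(day_vals.mean()) if len(day_vals) else math.nan,
                "full_day_mean": float(grp["buzz_per_hour"].mean()),
            }
        )
    return pd.DataFrame(rows).sort_values("iso_week", ignore_index=True)
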