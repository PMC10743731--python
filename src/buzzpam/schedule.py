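"""Duty-cycled recording schedule.

The device records in fixed on/off cycles that restart at each daily
period boundary. The default regime records 12 min per hour between
06:00 and 21:00 (20% duty cycle) and 4 min per hour between 21:00 and
06:00, for 216 recorded minutes per day. On-windows are half-open
[start, end); an instant exactly on a boundary belongs to the later
state.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Sequence

__all__ = ["SchedulePeriod", "DutyCycleSchedule"]

_DAY_MIN = 24 * 60


def _parse_hhmm(s: str) -> float:
    h, m = s.split(":")
    return int(h) * 60 + int(m)


def _fmt_hhmm(minute: float) -> str:
    minute = int(minute) % _DAY_MIN
    return f"{minute // 60:02d}:{minute % 60:02d}"


@dataclass(frozen=True)
class SchedulePeriod:
    """One daily period with its on/off cycle, in minutes of day.

    ``start_minute``/``end_minute`` are minutes after local midnight;
    a period with end <= start wraps past midnight (e.g. 21:00-06:00).
    """

    start_minute: float
    end_minute: float
    on_minutes: float
    off_minutes: float

    def __post_init__(self) -> None:
        if self.on_minutes < 0 or self.off_minutes < 0:
            raise ValueError("on/off minutes must be non-negative")
        if self.on_minutes + self.off_minutes <= 0:
            raise ValueError("cycle length must be positive")
        if not (0 <= self.start_minute < _DAY_MIN and 0 <= self.end_minute <= _DAY_MIN):
            raise ValueError("period boundaries must lie within the day")

    @property
    def length_minutes(self) -> float:
        length = self.end_minute - self.start_minute
        return length if length > 0 else length + _DAY_MIN

    @property
    def cycle_minutes(self) -> float:
        return self.on_minutes + self.off_minutes


@dataclass(frozen=True)
class DutyCycleSchedule:
    """A set of daily periods that tile the 24 h day without gap or overlap."""

    periods: tuple[SchedulePeriod, ...]

    def __init__(self, periods: Sequence[SchedulePeriod]):
        periods = tuple(periods)
        if not periods:
            raise ValueError("schedule needs at least one period")
        if abs(sum(p.length_minutes for p in periods) - _DAY_MIN) > 1e-9:
            raise ValueError("periods must tile exactly 24 hours")
        # overlap check: walk boundaries around the clock
        starts = sorted(p.start_minute for p in periods)
        for p in periods:
            nxt = starts[(starts.index(p.start_minute) + 1) % len(starts)]
            expected = p.start_minute + p.length_minutes
            if abs(expected % _DAY_MIN - nxt % _DAY_MIN) > 1e-9:
                raise ValueError("periods overlap or leave a gap")
        object.__setattr__(self, "periods", periods)

    @classmethod
    def default(cls) -> "DutyCycleSchedule":
        """12 on / 48 off from 06:00 to 21:00; 4 on / 56 off overnight."""
        return cls(
            [
                SchedulePeriod(6 * 60, 21 * 60, 12, 48),
                SchedulePeriod(21 * 60, 6 * 60, 4, 56),
            ]
        )

    @classmethod
    def from_dicts(cls, entries: Sequence[dict]) -> "DutyCycleSchedule":
        """Build from config entries like
        ``{"start": "06:00", "end": "21:00", "on_min": 12, "off_min": 48}``.
        """
        return cls(
            [
                SchedulePeriod(
                    _parse_hhmm(e["start"]),
                    _parse_hhmm(e["end"]),
                    float(e["on_min"]),
                    float(e["off_min"]),
                )
                for e in entries
            ]
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "DutyCycleSchedule":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        if isinstance(data, dict) and "periods" in data:
            data = data["periods"]
        return cls.from_dicts(data)

    def to_dicts(self) -> list[dict]:
        return [
            {
                "start": _fmt_hhmm(p.start_minute),
                "end": _fmt_hhmm(p.end_minute),
                "on_min": p.on_minutes,
                "off_min": p.off_minutes,
            }
            for p in self.periods
        ]

    # -- core queries ------------------------------------------------------

    def _period_instances(
        self, day: date
    ) -> list[tuple[datetime, datetime, SchedulePeriod]]:
        """Concrete (start, end) datetimes of each period instance
        anchored on ``day`` (a wrapping period runs into the next day)."""
        midnight = datetime.combine(day, time(0))
        out = []
        for p in self.periods:
            start = midnight + timedelta(minutes=p.start_minute)
            end = start + timedelta(minutes=p.length_minutes)
            out.append((start, end, p))
        return out

    def on_windows(self, day: date) -> list[tuple[datetime, datetime]]:
        """All on-windows starting within ``day`` (local midnight to
        midnight). Each cycle contributes one window of ``on_minutes``
        beginning at the cycle boundary; cycles restart at each period
        start. Windows of a wrapping period that begin after midnight
        are attributed to the day they start on.
        """
        day_start = datetime.combine(day, time(0))
        day_end = day_start + timedelta(days=1)
        windows = []
        for anchor in (day - timedelta(days=1), day):
            for pstart, pend, p in self._period_instances(anchor):
                if p.on_minutes <= 0:
                    continue
                t = pstart
                cycle = timedelta(minutes=p.cycle_minutes)
                on = timedelta(minutes=p.on_minutes)
                while t < pend:
                    if day_start <= t < day_end:
                        windows.append((t, min(t + on, pend)))
                    t += cycle
        windows.sort()
        return windows

    def recorded_minutes(self, start: datetime, end: datetime) -> float:
        """Total on-air minutes overlapping [start, end).

        Additive over disjoint intervals; equals 216 for a full default
        day and 12 for any hour-aligned daytime hour.
        """
        if start >= end:
            raise ValueError("interval start must precede end")
        total = timedelta(0)
        day = start.date() - timedelta(days=1)
        while day <= end.date():
            for pstart, pend, p in self._period_instances(day):
                if p.on_minutes <= 0 or pend <= start or pstart >= end:
                    continue
                cycle = timedelta(minutes=p.cycle_minutes)
                on = timedelta(minutes=p.on_minutes)
                t = pstart
                while t < pend:
                    w_end = min(t + on, pend)
                    lo = max(t, start)
                    hi = min(w_end, end)
                    if hi > lo:
                        total += hi - lo
                    t += cycle
            day += timedelta(days=1)
        return total.total_seconds() / 60.0

    def is_recorded(self, t: datetime) -> bool:
        """True iff ``t`` falls inside an on-window ([start, end))."""
        minute = t.hour * 60 + t.minute + t.second / 60 + t.microsecond / 6e7
        for p in self.periods:
            offset = (minute - p.start_minute) % _DAY_MIN
            if offset < p.length_minutes:
                return offset % p.cycle_minutes < p.on_minutes
        raise AssertionError("periods tile the day; unreachable")
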