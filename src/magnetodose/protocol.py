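"""Intermittent magnetic-stimulation schedules.

Two shapes of schedule occur in practice: a cyclic ON/OFF pattern within a
single continuous session (e.g. 15 min ON / 15 min OFF repeated 24 times
over 12 h during imaging) and clock-anchored daily sessions repeated over a
treatment course (e.g. 15 min at 6:00, 12:00 and 18:00 for 14 days). Both
reduce to an ordered list of ON intervals on a continuous minutes axis,
which is what the dose integrals consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "CyclicProtocol",
    "DailySessionProtocol",
    "build_schedule",
    "schedule_summary",
    "schedule_span_minutes",
    "write_schedule_csv",
    "read_schedule_csv",
]

MIN_PER_DAY = 24 * 60.0


@dataclass(frozen=True)
class CyclicProtocol:
    """ON/OFF cycling within one continuous session.

    Tiles (on, off) pairs from t=0 until ``total_span_h`` is exhausted; a
    final partial ON interval is truncated, not dropped.
    """

    on_duration_min: float = 15.0
    off_duration_min: float = 15.0
    total_span_h: float = 12.0

    def __post_init__(self) -> None:
        if self.on_duration_min <= 0 or self.off_duration_min <= 0:
            raise ValueError("on/off durations must be > 0")
        if self.total_span_h <= 0:
            raise ValueError("total_span_h must be > 0")


@dataclass(frozen=True)
class DailySessionProtocol:
    """Clock-anchored sessions repeated daily.

    ``session_start_times`` are naive local clock times as "HH:MM" strings
    on a day grid (no timezone handling); day 1 starts at t=0.
    """

    session_start_times: tuple[str, ...] = ("06:00", "12:00", "18:00")
    session_duration_min: float = 15.0
    n_days: int = 14

    def __post_init__(self) -> None:
        if self.session_duration_min <= 0:
            raise ValueError("session_duration_min must be > 0")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        starts = sorted(_clock_to_minutes(t) for t in self.session_start_times)
        for a, b in zip(starts, starts[1:]):
            if a + self.session_duration_min > b:
                raise ValueError(
                    f"sessions overlap: start {a} min + {self.session_duration_min} "
                    f"min runs past the next start at {b} min")
        if starts and starts[-1] + self.session_duration_min > MIN_PER_DAY:
            raise ValueError("last daily session runs past midnight")


def _clock_to_minutes(hhmm: str) -> float:
    h, m = hhmm.split(":")
    h, m = int(h), int(m)
    if not (0 <= h < 24 and 0 <= m < 60):
        raise ValueError(f"bad clock time {hhmm!r}")
    return 60.0 * h + m


def build_schedule(protocol) -> list[tuple[float, float]]:
    """Expand a protocol into sorted, non-overlapping ON intervals (minutes).

    Deterministic and idempotent: the same protocol always yields the same
    interval list.
    """
    if isinstance(protocol, CyclicProtocol):
        span = protocol.total_span_h * 60.0
        period = protocol.on_duration_min + protocol.off_duration_min
        intervals = []
        t = 0.0
        while t < span:
            intervals.append((t, min(t + protocol.on_duration_min, span)))
            t += period
        return intervals
    if isinstance(protocol, DailySessionProtocol):
        starts = sorted(_clock_to_minutes(s) for s in protocol.session_start_times)
        return [
            (day * MIN_PER_DAY + s, day * MIN_PER_DAY + s + protocol.session_duration_min)
            for day in range(protocol.n_days)
            for s in starts
        ]
    raise TypeError(f"unknown protocol type {type(protocol).__name__}")


def schedule_span_minutes(protocol) -> float:
    """Total span of the schedule's time axis, in minutes."""
    if isinstance(protocol, CyclicProtocol):
        return protocol.total_span_h * 60.0
    if isinstance(protocol, DailySessionProtocol):
        return protocol.n_days * MIN_PER_DAY
    raise TypeError(f"unknown protocol type {type(protocol).__name__}")


def schedule_summary(intervals: Sequence[tuple[float, float]],
                     span_min: float | None = None) -> dict:
    """Count, total ON time and duty cycle of an interval list.

    ``span_min`` defaults to the end of the last interval; an empty schedule
    summarizes to all zeros.
    """
    if not intervals:
        return {"n_on": 0, "total_on_min": 0.0, "duty_cycle": 0.0}
    total_on = sum(b - a for a, b in intervals)
    if span_min is None:
        span_min = intervals[-1][1]
    return {
        "n_on": len(intervals),
        "total_on_min": total_on,
        "duty_cycle": total_on / span_min if span_min > 0 else 0.0,
    }


def write_schedule_csv(intervals: Sequence[tuple[float, float]],
                       path: str | Path) -> None:
    pd.DataFrame(intervals, columns=["start_min", "end_min"]).to_csv(path, index=False)


def read_schedule_csv(path: str | Path) -> list[tuple[float, float]]:
    df = pd.read_csv(path)
    return [(float(a), float(b)) for a, b in zip(df["start_min"], df["end_min"])]
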