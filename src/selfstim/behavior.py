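"""Operant self-stimulation behavior metrics.

Works on timestamped nosepoke logs from two-port operant boxes in which
poking the active port triggers a fixed-duration laser reinforcer (with a
re-initiation lockout equal to the laser duration), and the inactive port
does nothing. Provides poke counts, cumulative response curves,
inter-poke intervals, burst segmentation, extinction-preference metrics
and the subject-exclusion QC rules, plus a small model-object wrapper for
per-session summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import InputError

__all__ = [
    "EventLog",
    "BurstSet",
    "SessionMetrics",
    "count_pokes",
    "interpoke_intervals",
    "detect_bursts",
    "cumulative_curve",
    "session_metrics",
    "extinction_metrics",
    "exclusion_qc",
    "OperantSessionModel",
    "OperantSessionResults",
]

SIDES = ("active", "inactive")

TRAINING_DURATION = 1800.0  # 30 min
EXTINCTION_DURATION = 900.0  # 15 min


@dataclass(frozen=True)
class EventLog:
    """Timestamped nosepokes of one session.

    ``events`` is a sequence of ``(time_s, side)`` with side in
    {"active", "inactive"}; for extinction sessions "active" denotes the
    previously laser-paired side. Consecutive same-side pokes must be at
    least ``laser_duration`` apart (the box cannot register a re-entry
    during the laser, nor during the equivalent lapse on the inactive
    side).
    """

    session_id: str
    session_duration: float
    events: tuple[tuple[float, str], ...]
    laser_duration: float = 1.0
    laser_paired: bool = True

    def __post_init__(self) -> None:
        if self.session_duration <= 0:
            raise InputError("session_duration must be positive")
        evts = tuple((float(t), str(s)) for t, s in self.events)
        times = np.array([t for t, _ in evts])
        if times.size:
            if np.any(np.diff(times) < 0):
                raise InputError(f"{self.session_id}: events must be ascending")
            if np.any(np.diff(times) == 0):
                raise InputError(f"{self.session_id}: simultaneous events")
            if times[0] < 0 or times[-1] >= self.session_duration:
                raise InputError(
                    f"{self.session_id}: events outside [0, session_duration)"
                )
        for side in {s for _, s in evts}:
            if side not in SIDES:
                raise InputError(f"{self.session_id}: unknown side {side!r}")
        for side in SIDES:
            st = self.side_times(evts, side)
            if st.size > 1 and np.any(np.diff(st) < self.laser_duration - 1e-9):
                raise InputError(
                    f"{self.session_id}: {side} pokes violate the "
                    f"{self.laser_duration} s lockout"
                )
        object.__setattr__(self, "events", evts)

    @staticmethod
    def side_times(events, side: str) -> np.ndarray:
        return np.array([t for t, s in events if s == side], dtype=float)

    def times(self, side: str) -> np.ndarray:
        if side not in SIDES:
            raise InputError(f"unknown side {side!r}")
        return self.side_times(self.events, side)

    @property
    def n_events(self) -> int:
        return len(self.events)


def count_pokes(log: EventLog) -> tuple[int, int]:
    """Exact (n_active, n_inactive) counts."""
    return int(log.times("active").size), int(log.times("inactive").size)


def interpoke_intervals(log: EventLog, side: str = "active") -> tuple[np.ndarray, Optional[float]]:
    """Successive onset-to-onset intervals on one side, and their mean
    (None with fewer than two pokes)."""
    t = log.times(side)
    intervals = np.diff(t)
    mean = float(intervals.mean()) if intervals.size else None
    return intervals, mean


@dataclass(frozen=True)
class BurstSet:
    """Bursts of responding: maximal runs of >= min_pokes same-side pokes
    whose successive onset-to-onset gaps are all below ``gap_threshold``."""

    gap_threshold: float
    bursts: tuple[tuple[float, float, int], ...]  # (start_s, end_s, n_pokes)

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)

    @property
    def mean_pokes_per_burst(self) -> Optional[float]:
        if not self.bursts:
            return None
        return float(np.mean([n for _, _, n in self.bursts]))


def detect_bursts(
    log: EventLog,
    side: str = "active",
    gap_threshold: float = 2.0,
    min_pokes: int = 2,
) -> BurstSet:
    """Segment one side's pokes into bursts.

    A run is maximal: it is terminated exactly at the first gap
    ``>= gap_threshold``. Runs with at least ``min_pokes`` pokes are
    reported as bursts.
    """
    if gap_threshold <= 0:
        raise InputError("gap_threshold must be positive")
    t = log.times(side)
    bursts: list[tuple[float, float, int]] = []
    if t.size:
        run_start = 0
        for i in range(1, t.size + 1):
            if i == t.size or t[i] - t[i - 1] >= gap_threshold:
                n = i - run_start
                if n >= min_pokes:
                    bursts.append((float(t[run_start]), float(t[i - 1]), n))
                run_start = i
    return BurstSet(gap_threshold, tuple(bursts))


def cumulative_curve(
    log: EventLog, side: str = "active", dt: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Running poke count on a regular time grid covering the session.

    Returns (grid, counts) where ``counts[i]`` is the number of pokes at
    or before ``grid[i]``; non-decreasing with final value equal to the
    side's total count.
    """
    grid = np.arange(0.0, log.session_duration + dt, dt)
    t = log.times(side)
    counts = np.searchsorted(t, grid, side="right")
    return grid, counts


@dataclass(frozen=True)
class SessionMetrics:
    session_id: str
    n_active: int
    n_inactive: int
    poke_rate: float  # total pokes per minute
    active_rate: float  # active pokes per minute
    mean_ipi: Optional[float]  # active-side inter-poke interval, seconds
    cumulative: tuple[np.ndarray, np.ndarray]


def session_metrics(log: EventLog) -> SessionMetrics:
    """Headline per-session metrics."""
    n_a, n_i = count_pokes(log)
    minutes = log.session_duration / 60.0
    _, mean_ipi = interpoke_intervals(log, "active")
    return SessionMetrics(
        session_id=log.session_id,
        n_active=n_a,
        n_inactive=n_i,
        poke_rate=(n_a + n_i) / minutes,
        active_rate=n_a / minutes,
        mean_ipi=mean_ipi,
        cumulative=cumulative_curve(log),
    )


def extinction_metrics(
    training_log: EventLog, extinction_log: EventLog
) -> dict:
    """Preference for the previously laser-paired side under extinction.

    The extinction log keeps the training side labels ("active" = the
    previously laser-paired port, now inert). The preference ratio is
    prev-active / total pokes; with no pokes at all it is reported as 0.5
    and flagged indeterminate.
    """
    if extinction_log.laser_paired:
        raise InputError("extinction log must have laser_paired=False")
    n_prev, n_other = count_pokes(extinction_log)
    total = n_prev + n_other
    flagged = total == 0
    ratio = 0.5 if flagged else n_prev / total
    return {
        "training_session": training_log.session_id,
        "extinction_session": extinction_log.session_id,
        "n_prev_active": n_prev,
        "n_other": n_other,
        "preference_ratio": ratio,
        "indeterminate": flagged,
    }


def exclusion_qc(
    daily_logs: Sequence[EventLog],
    decline_fraction: float = 0.5,
    min_rate_per_min: float = 1.0,
) -> dict:
    """Subject-exclusion rules over four consecutive daily sessions.

    A subject is excluded when the day-4 active count has declined to
    below ``decline_fraction`` of the day-1 count, or when the average
    active-poke rate over the four sessions is below
    ``min_rate_per_min`` pokes/min.
    """
    if len(daily_logs) != 4:
        raise InputError("exclusion QC requires exactly 4 daily sessions")
    active = [count_pokes(log)[0] for log in daily_logs]
    total_minutes = sum(log.session_duration for log in daily_logs) / 60.0
    mean_rate = sum(active) / total_minutes
    declined = active[3] < decline_fraction * active[0]
    low_rate = mean_rate < min_rate_per_min
    return {
        "active_counts": active,
        "mean_rate_per_min": mean_rate,
        "declined": bool(declined),
        "low_rate": bool(low_rate),
        "excluded": bool(declined or low_rate),
    }


class OperantSessionModel:
    """Per-session behavioral summary model.

    Thin model-object wrapper: build from an :class:`EventLog` (or a
    long-format DataFrame), ``fit()`` computes counts, rates, intervals,
    bursts at the configured thresholds, and the cumulative curve.
    """

    def __init__(
        self,
        log: EventLog,
        burst_thresholds: tuple[float, ...] = (2.0, 6.0),
    ) -> None:
        self.log = log
        self.burst_thresholds = burst_thresholds

    @classmethod
    def from_dataframe(
        cls,
        events: pd.DataFrame,
        session_id: str,
        session_duration: float = TRAINING_DURATION,
        laser_duration: float = 1.0,
        laser_paired: bool = True,
        burst_thresholds: tuple[float, ...] = (2.0, 6.0),
    ) -> "OperantSessionModel":
        """Build from a table with columns ``time_s`` and ``side``."""
        log = EventLog(
            session_id=session_id,
            session_duration=session_duration,
            events=tuple(zip(events["time_s"], events["side"])),
            laser_duration=laser_duration,
            laser_paired=laser_paired,
        )
        return cls(log, burst_thresholds)

    def fit(self) -> "OperantSessionResults":
        metrics = session_metrics(self.log)
        bursts = {
            th: detect_bursts(self.log, "active", th)
            for th in self.burst_thresholds
        }
        return OperantSessionResults(self, metrics, bursts)


@dataclass
class OperantSessionResults:
    model: OperantSessionModel
    metrics: SessionMetrics
    bursts: dict[float, BurstSet]

    def summary(self) -> str:
        m = self.metrics
        lines = [
            f"Session {m.session_id} "
            f"({self.model.log.session_duration / 60:g} min)",
            "=" * 48,
            f"Active pokes:   {m.n_active}  ({m.active_rate:.2f}/min)",
            f"Inactive pokes: {m.n_inactive}",
            "Mean inter-poke interval (active): "
            + (f"{m.mean_ipi:.1f} s" if m.mean_ipi is not None else "n/a"),
        ]
        for th, bs in self.bursts.items():
            mean = bs.mean_pokes_per_burst
            lines.append(
                f"Bursts (<{th:g} s gaps): {bs.n_bursts}"
                + (f", {mean:.2f} pokes/burst" if mean is not None else "")
            )
        return "\n".join(lines)

    def plot_cumulative(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid, counts = self.metrics.cumulative
        ax.step(grid / 60.0, counts, where="post")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("cumulative active pokes")
        return ax
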