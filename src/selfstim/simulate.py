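"""Synthetic data with known ground truth.

Generates the three kinds of data the analysis modules consume — spike
trains under a repeated-stimulation protocol, operant nosepoke sessions,
and open-field position tracks — from simple generative models whose
parameters are the recovery targets of the test suite.

Spike trains are piecewise-homogeneous Poisson processes: a unit fires at
its baseline rate everywhere except during a per-trial effect window
(onset delay + fixed duration) where the rate steps to the response rate.
The behavioral agent is a deliberately minimal two-clock reinforcement
scheme (see :class:`AgentSpec`); it reproduces the qualitative signatures
of self-stimulation behavior (within-session growth of active responding,
neglect of the inactive port, extinction preference) without claiming to
model animal learning.

All generators take an explicit seed and are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .behavior import EventLog
from .config import InputError, StimulusProtocol
from .locomotion import Epoch, TrackSeries
from .spikes import SpikeTrain

__all__ = [
    "UnitSpec",
    "AgentSpec",
    "simulate_unit",
    "simulate_population",
    "simulate_operant_session",
    "simulate_extinction_session",
    "simulate_track",
]


@dataclass(frozen=True)
class UnitSpec:
    """Ground-truth description of one simulated unit.

    ``response_kind`` is "excited", "inhibited" or "null"; during each
    trial's effect window (``[onset + onset_delay, onset + onset_delay +
    effect_duration)``) the rate steps from ``base_rate`` to
    ``response_rate``.
    """

    unit_id: str
    base_rate: float
    response_kind: str = "null"
    response_rate: Optional[float] = None
    onset_delay: float = 0.0
    effect_duration: float = 1.0

    def __post_init__(self) -> None:
        if self.base_rate < 0:
            raise InputError("base_rate must be nonnegative")
        rr = self.base_rate if self.response_rate is None else self.response_rate
        if rr < 0:
            raise InputError("response_rate must be nonnegative")
        if self.response_kind == "excited" and rr <= self.base_rate:
            raise InputError("excited units need response_rate > base_rate")
        if self.response_kind == "inhibited" and rr >= self.base_rate:
            raise InputError("inhibited units need response_rate < base_rate")
        if self.response_kind not in ("excited", "inhibited", "null"):
            raise InputError(f"unknown response_kind {self.response_kind!r}")
        if not 0 <= self.onset_delay <= 0.1:
            raise InputError("onset_delay must lie in [0, 0.1] s")
        object.__setattr__(self, "response_rate", rr)


def _homogeneous_poisson(rate: float, t0: float, t1: float,
                         rng: np.random.Generator) -> np.ndarray:
    if rate <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(rate * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, n))


def simulate_unit(
    spec: UnitSpec,
    protocol: StimulusProtocol,
    seed: int | np.random.Generator = 0,
) -> SpikeTrain:
    """Sample one piecewise-homogeneous Poisson spike train.

    Baseline-rate spikes are drawn over the whole recording, removed
    inside each trial's effect window, and replaced by response-rate
    spikes there — an exact sampler for the stepwise rate function.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    duration = protocol.recording_span
    spikes = _homogeneous_poisson(spec.base_rate, 0.0, duration, rng)
    pieces = [spikes]
    keep = np.ones(spikes.size, dtype=bool)
    for onset in protocol.onset_times:
        a = onset + spec.onset_delay
        b = a + spec.effect_duration
        keep &= ~((spikes >= a) & (spikes < b))
        pieces.append(_homogeneous_poisson(spec.response_rate, a, min(b, duration), rng))
    pieces[0] = spikes[keep]
    times = np.sort(np.concatenate(pieces))
    return SpikeTrain(spec.unit_id, times, duration)


def simulate_population(
    n_units: int,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    protocol: StimulusProtocol | None = None,
    seed: int = 0,
    base_rate_range: tuple[float, float] = (8.0, 25.0),
    excited_gain_range: tuple[float, float] = (2.0, 4.0),
    inhibited_residual_range: tuple[float, float] = (0.0, 0.3),
    onset_delays: Sequence[float] = (0.0, 0.02, 0.05),
) -> tuple[list[SpikeTrain], pd.DataFrame]:
    """Simulate a mixed population with ground truth.

    ``fractions`` are the (excited, inhibited, null) proportions; class
    counts are assigned deterministically (largest remainder) and the unit
    order shuffled. Excited units multiply their baseline rate by a factor
    drawn from ``excited_gain_range``; inhibited units drop to a fraction
    of baseline drawn from ``inhibited_residual_range``. Onset delays are
    drawn uniformly from ``onset_delays``.

    Returns the spike trains and a ground-truth table (one row per unit).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise InputError("fractions must sum to 1")
    protocol = protocol or StimulusProtocol.regular()
    rng = np.random.default_rng(seed)

    ideal = np.array(fractions) * n_units
    counts = np.floor(ideal).astype(int)
    remainder = ideal - counts
    for k in np.argsort(-remainder)[: n_units - counts.sum()]:
        counts[k] += 1
    kinds = np.repeat(["excited", "inhibited", "null"], counts)
    rng.shuffle(kinds)

    trains, rows = [], []
    for i, kind in enumerate(kinds):
        base = rng.uniform(*base_rate_range)
        if kind == "excited":
            resp = base * rng.uniform(*excited_gain_range)
        elif kind == "inhibited":
            resp = base * rng.uniform(*inhibited_residual_range)
        else:
            resp = base
        delay = float(rng.choice(np.asarray(onset_delays)))
        spec = UnitSpec(
            unit_id=f"unit{i:04d}",
            base_rate=float(base),
            response_kind=kind,
            response_rate=float(resp),
            onset_delay=delay,
            effect_duration=protocol.stim_duration - delay,
        )
        trains.append(simulate_unit(spec, protocol, rng))
        rows.append({
            "unit_id": spec.unit_id,
            "response_kind": kind,
            "base_rate": spec.base_rate,
            "response_rate": spec.response_rate,
            "onset_delay": delay,
        })
    return trains, pd.DataFrame(rows)


@dataclass(frozen=True)
class AgentSpec:
    """Two-clock operant agent.

    Each side has an exponential poke clock. After every reinforced active
    poke the active rate increases by ``learning_gain`` pokes/min and the
    inactive rate is multiplied by ``inactive_decay``; an unreinforced
    agent keeps both rates fixed. Pokes attempted during a side's
    ``laser_duration`` lockout are suppressed (not logged, no learning),
    mirroring a box that cannot register a re-entry until the laser turns
    off.

    The defaults emulate a well-trained self-stimulating subject
    (reinforced: roughly 100-200 active pokes and a handful of inactive
    pokes per 30-min session) or a control subject (``reinforced=False``
    with a low symmetric base rate: a few tens of pokes split evenly).
    """

    base_poke_rate: float = 2.0  # pokes/min per side
    learning_gain: float = 0.05  # pokes/min added per reinforced poke
    inactive_decay: float = 0.97  # multiplicative, per reinforced poke
    reinforced: bool = True

    def __post_init__(self) -> None:
        if self.base_poke_rate < 0 or self.learning_gain < 0:
            raise InputError("rates and gains must be nonnegative")
        if not 0 < self.inactive_decay <= 1:
            raise InputError("inactive_decay must lie in (0, 1]")


def _run_session(
    rate_active: float,
    rate_inactive: float,
    spec: AgentSpec,
    duration: float,
    laser_duration: float,
    reinforced: bool,
    rng: np.random.Generator,
    session_id: str,
    laser_paired: bool,
) -> tuple[EventLog, float, float]:
    r_a, r_i = rate_active / 60.0, rate_inactive / 60.0  # per second
    t = 0.0
    lockout_end = {"active": 0.0, "inactive": 0.0}
    events: list[tuple[float, str]] = []
    while True:
        dt_a = rng.exponential(1.0 / r_a) if r_a > 0 else np.inf
        dt_i = rng.exponential(1.0 / r_i) if r_i > 0 else np.inf
        if not np.isfinite(min(dt_a, dt_i)):
            break
        if dt_a <= dt_i:
            side, t = "active", t + dt_a
        else:
            side, t = "inactive", t + dt_i
        if t >= duration:
            break
        if t < lockout_end[side]:
            continue  # suppressed: box cannot register the entry
        events.append((t, side))
        lockout_end[side] = t + laser_duration
        if side == "active" and reinforced:
            r_a += spec.learning_gain / 60.0
            r_i *= spec.inactive_decay
    log = EventLog(
        session_id=session_id,
        session_duration=duration,
        events=tuple(events),
        laser_duration=laser_duration,
        laser_paired=laser_paired,
    )
    return log, r_a * 60.0, r_i * 60.0


def simulate_operant_session(
    spec: AgentSpec,
    duration: float = 1800.0,
    laser_duration: float = 1.0,
    seed: int | np.random.Generator = 0,
    session_id: str = "session",
) -> tuple[EventLog, dict]:
    """Simulate one training session.

    Returns the event log and a ground-truth record with the exact poke
    tallies and the final (learned) per-side rates, which can seed an
    extinction run.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    log, final_a, final_i = _run_session(
        spec.base_poke_rate, spec.base_poke_rate, spec, duration,
        laser_duration, spec.reinforced, rng, session_id, laser_paired=True,
    )
    n_a = sum(1 for _, s in log.events if s == "active")
    n_i = len(log.events) - n_a
    truth = {
        "n_active": n_a,
        "n_inactive": n_i,
        "final_active_rate": final_a,
        "final_inactive_rate": final_i,
    }
    return log, truth


def simulate_extinction_session(
    spec: AgentSpec,
    learned_rates: tuple[float, float],
    duration: float = 900.0,
    laser_duration: float = 1.0,
    seed: int | np.random.Generator = 0,
    session_id: str = "extinction",
) -> EventLog:
    """Simulate an extinction session: reinforcement removed, learning
    frozen, the agent replays its learned per-side rates. The "active"
    label denotes the previously laser-paired side."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    log, _, _ = _run_session(
        learned_rates[0], learned_rates[1], spec, duration,
        laser_duration, False, rng, session_id, laser_paired=False,
    )
    return log


def simulate_track(
    epochs: Sequence[Epoch],
    speeds: dict[str, float],
    sample_rate: float = 25.0,
    seed: int | np.random.Generator = 0,
    turn_sd: float = 0.5,
) -> TrackSeries:
    """Smooth random-walk track with per-epoch speed.

    Headings follow a wrapped Gaussian random walk (``turn_sd`` radians
    per step); each step's length is the current epoch's speed divided by
    the sample rate, so the realized path length inside an epoch equals
    speed x duration up to boundary discretization.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    for label, v in speeds.items():
        if v < 0:
            raise InputError(f"speed for {label!r} must be nonnegative")
    t0 = min(e.start_s for e in epochs)
    t1 = max(e.end_s for e in epochs)
    dt = 1.0 / sample_rate
    times = t0 + dt * np.arange(int(round((t1 - t0) * sample_rate)) + 1)

    def speed_at(t: float) -> float:
        for e in epochs:
            if e.start_s <= t < e.end_s:
                return speeds.get(e.label, 0.0)
        return 0.0

    headings = np.cumsum(rng.normal(0.0, turn_sd, times.size - 1))
    xy = np.zeros((times.size, 2))
    for i in range(times.size - 1):
        step = speed_at(times[i]) * dt
        xy[i + 1] = xy[i] + step * np.array(
            [np.cos(headings[i]), np.sin(headings[i])]
        )
    return TrackSeries(times, xy, tuple(epochs))
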