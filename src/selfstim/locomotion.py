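"""Open-field locomotion: per-epoch path length.

The stimulation-locomotion assay repeats cycles of pre-stimulation,
stimulation ("laser"), post-stimulation and recovery epochs while the
animal's position is tracked; the distance travelled is summed within
each epoch and pooled across same-label epochs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import InputError

__all__ = ["TrackSeries", "Epoch", "standard_stimulation_epochs", "epoch_distance"]

EPOCH_LABELS = ("pre", "laser", "post", "recovery")


@dataclass(frozen=True)
class Epoch:
    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise InputError("epoch end must exceed start")


def standard_stimulation_epochs(
    n_cycles: int = 5,
    pre: float = 10.0,
    laser: float = 10.0,
    post: float = 10.0,
    recovery: float = 30.0,
    t0: float = 0.0,
) -> tuple[Epoch, ...]:
    """Epochs of the repeated stimulation-locomotion assay: ``n_cycles``
    cycles of pre / laser / post followed by a recovery period."""
    epochs = []
    t = t0
    for _ in range(n_cycles):
        for label, dur in (("pre", pre), ("laser", laser),
                           ("post", post), ("recovery", recovery)):
            epochs.append(Epoch(label, t, t + dur))
            t += dur
    return tuple(epochs)


@dataclass(frozen=True)
class TrackSeries:
    """Position samples (time_s, x_cm, y_cm) with epoch labels."""

    times: np.ndarray
    xy: np.ndarray  # (n, 2) in cm
    epochs: tuple[Epoch, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        xy = np.asarray(self.xy, dtype=float)
        if t.ndim != 1 or xy.shape != (t.size, 2):
            raise InputError("times must be 1-D and xy of shape (n, 2)")
        if np.any(np.diff(t) <= 0):
            raise InputError("sample times must be strictly increasing")
        starts = sorted(e.start_s for e in self.epochs)
        for a, b in zip(sorted(self.epochs, key=lambda e: e.start_s)[:-1],
                        sorted(self.epochs, key=lambda e: e.start_s)[1:]):
            if b.start_s < a.end_s - 1e-9:
                raise InputError("epochs overlap")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "xy", xy)


def _clip_step(t0, t1, p0, p1, a, b):
    """Length of the segment p0->p1 restricted (by linear interpolation in
    time) to the interval [a, b]."""
    lo, hi = max(t0, a), min(t1, b)
    if hi <= lo:
        return 0.0
    frac = (hi - lo) / (t1 - t0)
    return frac * float(np.hypot(*(p1 - p0)))


def epoch_distance(track: TrackSeries) -> dict[str, float]:
    """Total path length (cm) per epoch label.

    Sums Euclidean step lengths between consecutive samples inside each
    epoch; steps straddling an epoch boundary are split proportionally in
    time. Distances are pooled across epochs sharing a label; samples
    outside every epoch contribute nothing.
    """
    t, xy = track.times, track.xy
    totals = {e.label: 0.0 for e in track.epochs}
    for i in range(t.size - 1):
        for e in track.epochs:
            d = _clip_step(t[i], t[i + 1], xy[i], xy[i + 1], e.start_s, e.end_s)
            if d:
                totals[e.label] += d
    return totals
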