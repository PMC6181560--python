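"""Stimulus-aligned single-unit spike-train analysis.

Implements the per-unit analysis chain for repeated-stimulation recordings:
trial-aligned binning, peri-event time histograms (PETH) with baseline
z-scoring, windowed firing-rate comparisons (paired t-test), the
normalized modulation index, and Poisson-confidence-interval latency
detection.

Conventions
-----------
* Bins are half-open on the right, ``[edge, edge + bin_width)``; a spike
  falling exactly on a stimulus onset belongs to the first post-onset bin.
* The baseline occupies ``[-baseline_window, 0)`` relative to onset.
* Rates are in Hz throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .config import AnalysisConfig, ConfigError, InputError, StimulusProtocol

__all__ = [
    "SpikeTrain",
    "Peth",
    "WindowedRates",
    "bin_edges",
    "bin_spike_counts",
    "compute_peth",
    "window_rates",
    "test_modulation",
    "modulation_index",
    "poisson_bounds",
    "detect_latency",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times of one unit over a continuous recording.

    ``spike_times`` are in seconds, sorted ascending, all within
    ``[0, recording_duration)``.
    """

    unit_id: str
    spike_times: np.ndarray
    recording_duration: float

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times, dtype=float)
        if t.ndim != 1:
            raise InputError("spike_times must be 1-D")
        if t.size and np.any(np.diff(t) < 0):
            raise InputError(f"unit {self.unit_id}: spike_times must be sorted")
        if t.size and (t[0] < 0 or t[-1] >= self.recording_duration):
            raise InputError(
                f"unit {self.unit_id}: spikes must lie in [0, recording_duration)"
            )
        object.__setattr__(self, "spike_times", t)

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


def bin_edges(cfg: AnalysisConfig, t_range: tuple[float, float]) -> np.ndarray:
    """Bin edges (seconds relative to onset) covering ``[t_min, t_max)``."""
    t_min, t_max = t_range
    n = (t_max - t_min) / cfg.bin_width
    if n <= 0 or abs(n - round(n)) > 1e-9:
        raise ConfigError("range bounds must be multiples of bin_width")
    return t_min + cfg.bin_width * np.arange(int(round(n)) + 1)


def bin_spike_counts(
    train: SpikeTrain,
    protocol: StimulusProtocol,
    cfg: AnalysisConfig,
    t_range: tuple[float, float] = (-1.0, 1.0),
) -> np.ndarray:
    """Count spikes per trial and per bin, aligned to stimulus onset.

    Returns an integer matrix of shape ``(n_trials, n_bins)`` where entry
    ``(i, b)`` counts spikes ``t`` with
    ``onset_i + edge_b <= t < onset_i + edge_{b+1}``.
    """
    edges = bin_edges(cfg, t_range)
    onsets = protocol.onset_times
    if onsets[0] + edges[0] < 0 or onsets[-1] + edges[-1] > train.recording_duration:
        raise InputError(
            f"unit {train.unit_id}: trial windows extend outside the recording "
            f"(duration {train.recording_duration} s)"
        )
    spikes = train.spike_times
    # searchsorted with side='left' realizes the half-open [edge, next_edge)
    # convention exactly, with no float-epsilon fudging.
    idx = np.searchsorted(spikes, onsets[:, None] + edges[None, :], side="left")
    return np.diff(idx, axis=1).astype(np.int64)


@dataclass(frozen=True)
class Peth:
    """Peri-event time histogram of one unit.

    ``z_rate`` is only defined when the baseline bins have non-zero
    variance (``baseline_sd > 0``); otherwise ``z_defined`` is False and
    ``z_rate`` is None rather than a NaN-filled array.
    """

    bin_edges: np.ndarray
    trial_counts: np.ndarray
    mean_rate: np.ndarray
    baseline_mean: float
    baseline_sd: float
    z_rate: Optional[np.ndarray]

    @property
    def n_trials(self) -> int:
        return self.trial_counts.shape[0]

    @property
    def z_defined(self) -> bool:
        return self.z_rate is not None

    def baseline_slice(self, baseline_window: float) -> slice:
        bw = self.bin_edges[1] - self.bin_edges[0]
        first = int(round((-baseline_window - self.bin_edges[0]) / bw))
        onset = int(round((0.0 - self.bin_edges[0]) / bw))
        return slice(first, onset)


def compute_peth(
    trial_counts: np.ndarray,
    cfg: AnalysisConfig,
    t_min: float = -1.0,
) -> Peth:
    """Trial-averaged PETH with baseline z-scoring.

    The trial-averaged rate per bin is ``sum_i counts[i, b] /
    (n_trials * bin_width)``. Baseline mean and sample SD (n-1 denominator)
    are taken over the bins covering ``[-baseline_window, 0)``; the z-scored
    rate is ``(mean_rate - baseline_mean) / baseline_sd`` where defined.
    """
    counts = np.asarray(trial_counts)
    if counts.ndim != 2 or (counts < 0).any():
        raise InputError("trial_counts must be a nonnegative 2-D matrix")
    n_trials, n_bins = counts.shape
    edges = t_min + cfg.bin_width * np.arange(n_bins + 1)
    n_base = cfg.n_bins(cfg.baseline_window)
    onset_bin = int(round((0.0 - t_min) / cfg.bin_width))
    if onset_bin < n_base or onset_bin > n_bins:
        raise ConfigError(
            f"binned range starts at {t_min} s: fewer than "
            f"{n_base} baseline bins before onset"
        )
    mean_rate = counts.sum(axis=0) / (n_trials * cfg.bin_width)
    base = mean_rate[onset_bin - n_base:onset_bin]
    baseline_mean = float(base.mean())
    baseline_sd = float(base.std(ddof=1)) if n_base > 1 else 0.0
    z = (mean_rate - baseline_mean) / baseline_sd if baseline_sd > 0 else None
    return Peth(edges, counts, mean_rate, baseline_mean, baseline_sd, z)


@dataclass(frozen=True)
class WindowedRates:
    """Per-trial firing rates in a post-onset response window vs baseline."""

    window_length: float
    per_trial_response_rate: np.ndarray
    per_trial_baseline_rate: np.ndarray

    @property
    def resp_mean(self) -> float:
        return float(self.per_trial_response_rate.mean())

    @property
    def base_mean(self) -> float:
        return float(self.per_trial_baseline_rate.mean())


def window_rates(
    trial_counts: np.ndarray,
    cfg: AnalysisConfig,
    window_length: float,
    t_min: float = -1.0,
) -> WindowedRates:
    """Per-trial rates: spikes in ``[0, window_length)`` / ``window_length``
    against spikes in ``[-baseline_window, 0)`` / ``baseline_window``."""
    counts = np.asarray(trial_counts)
    n_bins = counts.shape[1]
    onset_bin = int(round((0.0 - t_min) / cfg.bin_width))
    n_resp = cfg.n_bins(window_length)
    n_base = cfg.n_bins(cfg.baseline_window)
    if onset_bin < n_base or onset_bin + n_resp > n_bins:
        raise ConfigError("window not covered by the binned range")
    resp = counts[:, onset_bin:onset_bin + n_resp].sum(axis=1) / window_length
    base = counts[:, onset_bin - n_base:onset_bin].sum(axis=1) / cfg.baseline_window
    return WindowedRates(window_length, resp, base)


def test_modulation(wr: WindowedRates, alpha: float = 0.05) -> tuple[str, float]:
    """Classify a unit's response in one window by a paired t-test.

    Two-sided paired t-test of per-trial response vs baseline rates.
    ``p < alpha`` with a higher response mean is ``"excited"``, with a lower
    mean ``"inhibited"``; anything else is ``"unmodulated"``. When every
    per-trial difference is zero the t statistic is undefined and the unit
    is unmodulated with p reported as 1.
    """
    resp = wr.per_trial_response_rate
    base = wr.per_trial_baseline_rate
    if resp.size < 2:
        raise InputError("paired test requires at least 2 trials")
    diff = resp - base
    if np.all(diff == diff[0]):
        if diff[0] == 0:
            return "unmodulated", 1.0
        # constant non-zero difference: infinitely strong evidence
        p = 0.0
    else:
        p = float(stats.ttest_rel(resp, base).pvalue)
    if p < alpha:
        return ("excited" if wr.resp_mean > wr.base_mean else "inhibited"), p
    return "unmodulated", p


def modulation_index(resp_mean: float, base_mean: float) -> float:
    """Normalized rate contrast ``(resp - base) / (resp + base)`` in [-1, 1].

    Antisymmetric under swapping arguments; 0 when both rates are equal.
    The degenerate 0 Hz / 0 Hz case returns 0 by convention (callers that
    need to distinguish it should test the rates).
    """
    if resp_mean < 0 or base_mean < 0:
        raise InputError("rates must be nonnegative")
    total = resp_mean + base_mean
    if total == 0:
        return 0.0
    return (resp_mean - base_mean) / total


def poisson_bounds(lam: float, conf: float = 0.97) -> tuple[int, int]:
    """Equal-tailed two-sided Poisson confidence region for a count.

    ``lo`` is the smallest k with ``CDF(k) >= (1 - conf) / 2`` and ``hi``
    the smallest k with ``CDF(k) >= 1 - (1 - conf) / 2``; a count is
    "outside" the region when it is ``< lo`` or ``> hi``.
    """
    if lam < 0:
        raise InputError("lambda must be nonnegative")
    if not 0 < conf < 1:
        raise ConfigError("conf must lie in (0, 1)")
    tail = (1.0 - conf) / 2.0
    lo = int(stats.poisson.ppf(tail, lam))
    hi = int(stats.poisson.ppf(1.0 - tail, lam))
    return lo, hi


def detect_latency(
    trial_counts: np.ndarray,
    cfg: AnalysisConfig,
    t_min: float = -1.0,
) -> Optional[float]:
    """Latency to significant modulation, or None.

    The trial-summed count in each post-onset bin is compared against the
    two-sided Poisson region at ``cfg.poisson_conf`` for the expectation
    ``baseline_rate * bin_width * n_trials`` derived from the 1 s
    pre-onset baseline. The latency is the start time of the second bin of
    the earliest pair of consecutive bins that both fall outside the
    region, restricted to bins starting within
    ``[0, latency_search_window)``; None when no such pair exists.
    """
    counts = np.asarray(trial_counts)
    n_trials, n_bins = counts.shape
    onset_bin = int(round((0.0 - t_min) / cfg.bin_width))
    n_base = cfg.n_bins(cfg.baseline_window)
    n_search = cfg.n_bins(cfg.latency_search_window)
    if onset_bin < n_base or onset_bin + n_search > n_bins:
        raise ConfigError("binned range must cover the baseline and search window")
    summed = counts.sum(axis=0)
    baseline_rate = summed[onset_bin - n_base:onset_bin].sum() / (
        n_trials * cfg.baseline_window
    )
    lam = baseline_rate * cfg.bin_width * n_trials
    lo, hi = poisson_bounds(lam, cfg.poisson_conf)
    post = summed[onset_bin:onset_bin + n_search]
    outside = (post < lo) | (post > hi)
    for b in range(n_search - 1):
        if outside[b] and outside[b + 1]:
            return float((b + 1) * cfg.bin_width)
    return None
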