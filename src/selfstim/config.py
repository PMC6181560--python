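"""Experiment protocol and analysis configuration.

The default values describe the in vivo optogenetic protocol these tools
were designed around: 1 s of stimulation delivered every 10 s for 100
trials, analysed in 10 ms bins against a 1 s pre-stimulus baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StimulusProtocol", "AnalysisConfig"]


class ConfigError(ValueError):
    """Raised when an analysis configuration is internally inconsistent."""


class InputError(ValueError):
    """Raised when input data violate a documented precondition."""


@dataclass(frozen=True)
class StimulusProtocol:
    """Timing of a repeated-stimulation experiment.

    Parameters
    ----------
    onset_times : array-like of float
        Stimulus onset times in seconds, strictly increasing.
    stim_duration : float
        Duration of each stimulation epoch in seconds.
    inter_trial_interval : float
        Onset-to-onset spacing in seconds (informational; the onsets are
        authoritative).
    """

    onset_times: np.ndarray
    stim_duration: float = 1.0
    inter_trial_interval: float = 10.0

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onset_times, dtype=float)
        if onsets.ndim != 1 or onsets.size == 0:
            raise InputError("onset_times must be a non-empty 1-D sequence")
        if np.any(np.diff(onsets) <= 0):
            raise InputError("onset_times must be strictly increasing")
        if self.stim_duration <= 0:
            raise ConfigError("stim_duration must be positive")
        object.__setattr__(self, "onset_times", onsets)

    @property
    def n_trials(self) -> int:
        return int(self.onset_times.size)

    @classmethod
    def regular(
        cls,
        n_trials: int = 100,
        inter_trial_interval: float = 10.0,
        stim_duration: float = 1.0,
        first_onset: float = 2.0,
    ) -> "StimulusProtocol":
        """Evenly spaced protocol: ``n_trials`` onsets every ``inter_trial_interval`` s.

        ``first_onset`` leaves room for the pre-stimulus baseline window of
        the first trial.
        """
        onsets = first_onset + inter_trial_interval * np.arange(n_trials, dtype=float)
        return cls(onsets, stim_duration=stim_duration,
                   inter_trial_interval=inter_trial_interval)

    @property
    def recording_span(self) -> float:
        """Smallest recording duration that contains every trial plus 1 s margin."""
        return float(self.onset_times[-1] + self.inter_trial_interval)


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameters of the stimulus-response analysis.

    Attributes
    ----------
    bin_width : float
        PETH bin width in seconds (default 10 ms).
    baseline_window : float
        Length of the pre-onset baseline in seconds (default 1 s); the
        baseline occupies ``[-baseline_window, 0)`` relative to onset.
    response_windows : tuple of float
        Post-onset windows (seconds) over which modulation is tested.
    alpha : float
        Per-unit significance level for the paired test (uncorrected).
    poisson_conf : float
        Two-sided confidence level of the Poisson region used for latency
        detection (default 0.97, i.e. 1.5% in each tail).
    latency_search_window : float
        Latency is only reported within this many seconds of onset.
    """

    bin_width: float = 0.010
    baseline_window: float = 1.0
    response_windows: tuple[float, ...] = (0.020, 0.100, 1.000)
    alpha: float = 0.05
    poisson_conf: float = 0.97
    latency_search_window: float = 0.100

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ConfigError("bin_width must be positive")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if not 0 < self.poisson_conf < 1:
            raise ConfigError("poisson_conf must lie in (0, 1)")
        for w in (self.baseline_window, *self.response_windows,
                  self.latency_search_window):
            if w <= 0:
                raise ConfigError("windows must be positive")
            n = w / self.bin_width
            if abs(n - round(n)) > 1e-9:
                raise ConfigError(
                    f"window {w} s is not a multiple of bin_width {self.bin_width} s"
                )

    def n_bins(self, window: float) -> int:
        return int(round(window / self.bin_width))
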