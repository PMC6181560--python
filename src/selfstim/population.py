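"""Population-level stimulus-response analysis.

Ties the per-unit chain together across a recorded (or simulated)
population: every unit is binned, PETH'd, classified per response window,
assigned a modulation index and a latency, and the population is
summarized by response-type fractions, the mean z-scored PETH trace, and
a paired signed-rank test of stimulation-epoch vs baseline firing across
units.

The `StimulusResponseModel` / `StimulusResponseResults` pair presents the
same computation in the familiar model-object idiom: build the model from
the data, call ``fit()``, inspect the results table and ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig, InputError, StimulusProtocol
from .spikes import (
    Peth,
    SpikeTrain,
    bin_spike_counts,
    compute_peth,
    detect_latency,
    modulation_index,
    test_modulation,
    window_rates,
)

__all__ = [
    "PopulationSummary",
    "classify_population",
    "sort_units_for_display",
    "StimulusResponseModel",
    "StimulusResponseResults",
]

CLASS_ORDER = ("excited", "unmodulated", "inhibited")


@dataclass(frozen=True)
class PopulationSummary:
    """Counts/fractions per window, the population z trace, and the
    across-unit baseline-vs-stimulation signed-rank test."""

    n_units: int
    counts: dict[float, dict[str, int]]
    fractions: dict[float, dict[str, float]]
    mean_z_trace: Optional[np.ndarray]
    z_trace_edges: np.ndarray
    n_units_in_z: int
    wilcoxon_p: float


def _analyze_unit(
    train: SpikeTrain,
    protocol: StimulusProtocol,
    cfg: AnalysisConfig,
    t_range: tuple[float, float],
) -> tuple[dict, Peth]:
    counts = bin_spike_counts(train, protocol, cfg, t_range)
    peth = compute_peth(counts, cfg, t_min=t_range[0])
    rec: dict = {"unit_id": train.unit_id, "z_defined": peth.z_defined}
    for w in cfg.response_windows:
        wr = window_rates(counts, cfg, w, t_min=t_range[0])
        cls, p = test_modulation(wr, cfg.alpha)
        key = int(round(w * 1000))
        rec[f"class_{key}ms"] = cls
        rec[f"p_{key}ms"] = p
        rec[f"mi_{key}ms"] = modulation_index(wr.resp_mean, wr.base_mean)
        rec[f"resp_rate_{key}ms"] = wr.resp_mean
    rec["base_rate"] = window_rates(counts, cfg, cfg.response_windows[-1],
                                    t_min=t_range[0]).base_mean
    lat = detect_latency(counts, cfg, t_min=t_range[0])
    rec["latency_s"] = lat if lat is not None else np.nan
    return rec, peth


def classify_population(
    trains: Sequence[SpikeTrain],
    protocol: StimulusProtocol,
    cfg: AnalysisConfig | None = None,
    t_range: tuple[float, float] = (-1.0, 1.0),
) -> tuple[pd.DataFrame, PopulationSummary]:
    """Classify every unit and summarize the population.

    Returns
    -------
    units : DataFrame
        One row per unit with, per response window, the class
        (excited / inhibited / unmodulated), the paired-test p-value and
        the modulation index; plus the Poisson-CI latency (NaN if absent)
        and whether the z-scored PETH is defined.
    summary : PopulationSummary
        Response-type counts and fractions per window, the mean z-scored
        PETH trace over units with defined z (baseline-SD > 0), and the
        across-unit Wilcoxon signed-rank p-value comparing mean firing in
        the stimulation second vs the baseline second.
    """
    if len(trains) == 0:
        raise InputError("population must contain at least one unit")
    cfg = cfg or AnalysisConfig()

    records, peths = [], []
    for train in trains:
        rec, peth = _analyze_unit(train, protocol, cfg, t_range)
        records.append(rec)
        peths.append(peth)
    units = pd.DataFrame.from_records(records)

    counts: dict[float, dict[str, int]] = {}
    fractions: dict[float, dict[str, float]] = {}
    for w in cfg.response_windows:
        key = int(round(w * 1000))
        vc = units[f"class_{key}ms"].value_counts()
        c = {cls: int(vc.get(cls, 0)) for cls in CLASS_ORDER}
        counts[w] = c
        fractions[w] = {cls: c[cls] / len(units) for cls in CLASS_ORDER}

    z_traces = [p.z_rate for p in peths if p.z_defined]
    mean_z = np.mean(z_traces, axis=0) if z_traces else None

    # across-unit paired comparison of firing in [0, 1) vs [-1, 0)
    full = cfg.response_windows[-1]
    key = int(round(full * 1000))
    stim_rates = units[f"resp_rate_{key}ms"].to_numpy()
    base_rates = units["base_rate"].to_numpy()
    if len(trains) >= 2 and np.any(stim_rates != base_rates):
        wilcoxon_p = float(stats.wilcoxon(stim_rates, base_rates).pvalue)
    else:
        wilcoxon_p = 1.0

    summary = PopulationSummary(
        n_units=len(units),
        counts=counts,
        fractions=fractions,
        mean_z_trace=mean_z,
        z_trace_edges=peths[0].bin_edges,
        n_units_in_z=len(z_traces),
        wilcoxon_p=wilcoxon_p,
    )
    return units, summary


def sort_units_for_display(units: pd.DataFrame, window: float = 1.0) -> pd.DataFrame:
    """Order units for display: excited, then unmodulated, then inhibited,
    each block sorted by modulation index descending."""
    key = int(round(window * 1000))
    order = {cls: i for i, cls in enumerate(CLASS_ORDER)}
    df = units.copy()
    df["_rank"] = df[f"class_{key}ms"].map(order)
    df = df.sort_values(["_rank", f"mi_{key}ms"], ascending=[True, False],
                        kind="mergesort")
    return df.drop(columns="_rank").reset_index(drop=True)


class StimulusResponseModel:
    """Stimulus-response classification model for a population of units.

    Parameters
    ----------
    trains : sequence of SpikeTrain
    protocol : StimulusProtocol
    config : AnalysisConfig, optional
    """

    def __init__(
        self,
        trains: Sequence[SpikeTrain],
        protocol: StimulusProtocol,
        config: AnalysisConfig | None = None,
    ) -> None:
        if len(trains) == 0:
            raise InputError("population must contain at least one unit")
        self.trains = list(trains)
        self.protocol = protocol
        self.config = config or AnalysisConfig()

    @classmethod
    def from_dataframe(
        cls,
        spikes: pd.DataFrame,
        protocol: StimulusProtocol,
        config: AnalysisConfig | None = None,
        recording_duration: float | None = None,
    ) -> "StimulusResponseModel":
        """Build from a long-format table with columns ``unit_id`` and
        ``spike_time_s``."""
        duration = recording_duration or protocol.recording_span
        trains = [
            SpikeTrain(str(uid), np.sort(g["spike_time_s"].to_numpy()), duration)
            for uid, g in spikes.groupby("unit_id", sort=True)
        ]
        return cls(trains, protocol, config)

    def fit(self, t_range: tuple[float, float] = (-1.0, 1.0)) -> "StimulusResponseResults":
        units, summary = classify_population(
            self.trains, self.protocol, self.config, t_range
        )
        return StimulusResponseResults(self, units, summary)


@dataclass
class StimulusResponseResults:
    """Fitted per-unit classifications and population summary."""

    model: StimulusResponseModel
    units: pd.DataFrame
    population: PopulationSummary

    def sorted_units(self, window: float = 1.0) -> pd.DataFrame:
        return sort_units_for_display(self.units, window)

    def summary(self) -> str:
        cfg = self.model.config
        pop = self.population
        lines = [
            "Stimulus-response classification",
            "=" * 48,
            f"Units: {pop.n_units}   trials: {self.model.protocol.n_trials}   "
            f"bin: {cfg.bin_width * 1000:g} ms   alpha: {cfg.alpha:g}",
            f"Baseline vs stimulation (signed-rank, across units): "
            f"p = {pop.wilcoxon_p:.4g}",
            "",
            f"{'window':>8} {'excited':>10} {'unmod.':>10} {'inhibited':>10}",
        ]
        for w in cfg.response_windows:
            f = pop.fractions[w]
            c = pop.counts[w]
            lines.append(
                f"{w * 1000:>6g}ms "
                + " ".join(
                    f"{c[cls]:>4d} ({f[cls]:>4.0%})"
                    for cls in CLASS_ORDER
                )
            )
        lat = self.units["latency_s"].dropna()
        if len(lat):
            lines.append("")
            lines.append(
                f"Latency (n={len(lat)}): median "
                f"{lat.median() * 1000:.0f} ms, range "
                f"{lat.min() * 1000:.0f}-{lat.max() * 1000:.0f} ms"
            )
        return "\n".join(lines)

    def plot_z_heatmap(self, ax=None, window: float = 1.0):
        """Heatmap of z-scored PETHs, units ordered as in :meth:`sorted_units`."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        cfg = self.model.config
        order = self.sorted_units(window)["unit_id"]
        peths = {}
        for train in self.model.trains:
            counts = bin_spike_counts(train, self.model.protocol, cfg)
            peths[train.unit_id] = compute_peth(counts, cfg)
        rows = [
            peths[uid].z_rate if peths[uid].z_defined
            else np.zeros(peths[uid].mean_rate.size)
            for uid in order
        ]
        edges = self.population.z_trace_edges
        im = ax.imshow(
            np.asarray(rows), aspect="auto", cmap="coolwarm",
            extent=[edges[0], edges[-1], len(rows), 0], vmin=-5, vmax=5,
        )
        ax.axvline(0, color="k", lw=0.5)
        ax.set_xlabel("time from stimulus onset (s)")
        ax.set_ylabel("unit (sorted)")
        return im

    def plot_population_z(self, ax=None):
        """Mean z-scored PETH across units with defined z."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        edges = self.population.z_trace_edges
        centers = (edges[:-1] + edges[1:]) / 2
        ax.plot(centers, self.population.mean_z_trace, color="k")
        ax.axvspan(0, self.model.protocol.stim_duration, color="tab:blue", alpha=0.2)
        ax.set_xlabel("time from stimulus onset (s)")
        ax.set_ylabel("mean z-scored rate")
        return ax
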