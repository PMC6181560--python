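"""End-to-end orchestration: simulate -> analyze -> report.

`run_ephys` and `run_behavior` read the plain-text inputs, run the
analysis modules, and write deterministic TSV/JSON bundles. `RunConfig`
round-trips through YAML/JSON so a run is fully described by one file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as ssio
from .behavior import OperantSessionModel, exclusion_qc
from .config import AnalysisConfig, InputError
from .population import StimulusResponseModel, sort_units_for_display

log = logging.getLogger("selfstim")

__all__ = ["RunConfig", "run_ephys", "run_behavior"]


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    spikes_csv: str | None = None
    protocol_path: str | None = None
    recording_duration: float | None = None
    events_csv: list[str] = field(default_factory=list)
    meta_json: list[str] = field(default_factory=list)
    out_dir: str = "results"
    bin_width: float = 0.010
    baseline_window: float = 1.0
    response_windows: tuple[float, ...] = (0.020, 0.100, 1.000)
    alpha: float = 0.05
    poisson_conf: float = 0.97
    latency_search_window: float = 0.100
    burst_thresholds: tuple[float, ...] = (2.0, 6.0)
    seed: int = 0

    def analysis_config(self) -> AnalysisConfig:
        return AnalysisConfig(
            bin_width=self.bin_width,
            baseline_window=self.baseline_window,
            response_windows=tuple(self.response_windows),
            alpha=self.alpha,
            poisson_conf=self.poisson_conf,
            latency_search_window=self.latency_search_window,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["response_windows"] = list(self.response_windows)
        d["burst_thresholds"] = list(self.burst_thresholds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("response_windows", "burst_thresholds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict()))


def run_ephys(config: RunConfig) -> dict[str, Path]:
    """Analyze a spike-train bundle: per-unit TSV (units sorted by
    response type then 1 s modulation index), population JSON, and the
    z-scored PETH matrix TSV."""
    t0 = time.perf_counter()
    if not config.spikes_csv or not config.protocol_path:
        raise InputError("spikes_csv and protocol_path are required")
    cfg = config.analysis_config()
    protocol = ssio.read_protocol(config.protocol_path)
    duration = config.recording_duration or protocol.recording_span
    trains = ssio.read_spike_trains(config.spikes_csv, duration)
    log.info("run_ephys: %d units, %d trials", len(trains), protocol.n_trials)

    model = StimulusResponseModel(trains, protocol, cfg)
    results = model.fit()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    units_sorted = results.sorted_units(cfg.response_windows[-1])
    paths = {
        "units": out / "unit_responses.tsv",
        "population": out / "population_summary.json",
        "summary": out / "ephys_summary.txt",
    }
    ssio.write_unit_results(units_sorted, paths["units"], cfg.response_windows)
    ssio.write_population_summary(results.population, paths["population"])
    paths["summary"].write_text(results.summary() + "\n")
    log.info("run_ephys: done in %.2f s", time.perf_counter() - t0)
    return paths


def run_behavior(config: RunConfig) -> dict[str, Path]:
    """Analyze operant sessions: metrics TSV (one row per session), burst
    table TSV, and a QC JSON (flags computed when a subject has exactly
    four training sessions; otherwise a partial-QC warning is recorded)."""
    t0 = time.perf_counter()
    if not config.events_csv:
        raise InputError("at least one events_csv is required")
    if len(config.meta_json) != len(config.events_csv):
        raise InputError("one meta_json per events_csv is required")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    metrics, bursts, logs = [], {}, []
    for events_path, meta_path in zip(config.events_csv, config.meta_json):
        session_log = ssio.read_event_log(events_path, meta_path)
        logs.append(session_log)
        res = OperantSessionModel(session_log, config.burst_thresholds).fit()
        metrics.append(res.metrics)
        bursts[session_log.session_id] = res.bursts
    log.info("run_behavior: %d sessions", len(logs))

    qc: dict = {"n_sessions": len(logs)}
    if len(logs) == 4:
        qc.update(exclusion_qc(logs))
    else:
        qc["warning"] = "partial QC: exclusion rules need exactly 4 daily sessions"

    paths = {
        "metrics": out / "session_metrics.tsv",
        "bursts": out / "bursts.tsv",
        "qc": out / "qc_report.json",
    }
    ssio.write_session_metrics(metrics, paths["metrics"])
    ssio.write_bursts(bursts, paths["bursts"])
    paths["qc"].write_text(json.dumps(qc, indent=2))
    log.info("run_behavior: done in %.2f s", time.perf_counter() - t0)
    return paths
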