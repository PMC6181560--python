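"""Readers and writers for the plain-text interchange formats.

Spikes: long CSV (unit_id, spike_time_s). Protocol: CSV of onset_time_s
or JSON {stim_duration_s, iti_s, n_trials, first_onset_s}. Event logs:
CSV (session_id, time_s, side) plus a JSON sidecar with session metadata.
Tracks: CSV (time_s, x_cm, y_cm) plus an epochs JSON. Results go out as
TSV/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .behavior import BurstSet, EventLog, SessionMetrics
from .config import InputError, StimulusProtocol
from .locomotion import Epoch, TrackSeries
from .population import PopulationSummary
from .spikes import SpikeTrain

__all__ = [
    "read_spike_trains",
    "write_spike_trains",
    "read_protocol",
    "write_protocol",
    "read_event_log",
    "write_event_log",
    "read_track",
    "write_track",
    "write_unit_results",
    "write_population_summary",
    "write_session_metrics",
    "write_bursts",
]


def read_spike_trains(path: str | Path, recording_duration: float) -> list[SpikeTrain]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, ("unit_id", "spike_time_s"), path)
    return [
        SpikeTrain(str(uid), np.sort(g["spike_time_s"].to_numpy(dtype=float)),
                   recording_duration)
        for uid, g in df.groupby("unit_id", sort=True)
    ]


def write_spike_trains(trains: Sequence[SpikeTrain], path: str | Path) -> None:
    frames = [
        pd.DataFrame({"unit_id": t.unit_id, "spike_time_s": t.spike_times})
        for t in trains
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_protocol(path: str | Path) -> StimulusProtocol:
    path = Path(path)
    if path.suffix.lower() == ".json":
        meta = json.loads(path.read_text())
        return StimulusProtocol.regular(
            n_trials=int(meta["n_trials"]),
            inter_trial_interval=float(meta.get("iti_s", 10.0)),
            stim_duration=float(meta.get("stim_duration_s", 1.0)),
            first_onset=float(meta.get("first_onset_s", 2.0)),
        )
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, ("onset_time_s",), path)
    return StimulusProtocol(df["onset_time_s"].to_numpy(dtype=float))


def write_protocol(protocol: StimulusProtocol, path: str | Path) -> None:
    pd.DataFrame({"onset_time_s": protocol.onset_times}).to_csv(path, index=False)


def read_event_log(events_csv: str | Path, meta_json: str | Path,
                   session_id: str | None = None) -> EventLog:
    df = pd.read_csv(events_csv, float_precision="round_trip")
    _require(df, ("session_id", "time_s", "side"), events_csv)
    meta = json.loads(Path(meta_json).read_text())
    sid = session_id or str(df["session_id"].iloc[0]) if len(df) else (session_id or "session")
    sub = df[df["session_id"].astype(str) == sid] if len(df) else df
    return EventLog(
        session_id=sid,
        session_duration=float(meta["duration_s"]),
        events=tuple(zip(sub["time_s"].astype(float), sub["side"].astype(str))),
        laser_duration=float(meta.get("laser_duration_s", 1.0)),
        laser_paired=bool(meta.get("laser_paired", True)),
    )


def write_event_log(log: EventLog, events_csv: str | Path,
                    meta_json: str | Path) -> None:
    pd.DataFrame(
        {
            "session_id": log.session_id,
            "time_s": [t for t, _ in log.events],
            "side": [s for _, s in log.events],
        }
    ).to_csv(events_csv, index=False)
    Path(meta_json).write_text(json.dumps(
        {
            "duration_s": log.session_duration,
            "laser_duration_s": log.laser_duration,
            "laser_paired": log.laser_paired,
        },
        indent=2,
    ))


def read_track(track_csv: str | Path, epochs_json: str | Path) -> TrackSeries:
    df = pd.read_csv(track_csv, float_precision="round_trip")
    _require(df, ("time_s", "x_cm", "y_cm"), track_csv)
    epochs = tuple(
        Epoch(e["label"], float(e["start_s"]), float(e["end_s"]))
        for e in json.loads(Path(epochs_json).read_text())
    )
    return TrackSeries(
        df["time_s"].to_numpy(dtype=float),
        df[["x_cm", "y_cm"]].to_numpy(dtype=float),
        epochs,
    )


def write_track(track: TrackSeries, track_csv: str | Path,
                epochs_json: str | Path) -> None:
    pd.DataFrame(
        {"time_s": track.times, "x_cm": track.xy[:, 0], "y_cm": track.xy[:, 1]}
    ).to_csv(track_csv, index=False)
    Path(epochs_json).write_text(json.dumps(
        [{"label": e.label, "start_s": e.start_s, "end_s": e.end_s}
         for e in track.epochs],
        indent=2,
    ))


def write_unit_results(units: pd.DataFrame, path: str | Path,
                       windows: Sequence[float] = (0.020, 0.100, 1.000)) -> None:
    """Per-unit results TSV: one row per unit and window."""
    rows = []
    for _, u in units.iterrows():
        for w in windows:
            key = int(round(w * 1000))
            lat = u["latency_s"]
            rows.append({
                "unit_id": u["unit_id"],
                "window_ms": key,
                "class": u[f"class_{key}ms"],
                "p": u[f"p_{key}ms"],
                "modulation_index": u[f"mi_{key}ms"],
                "latency_ms": "" if pd.isna(lat) else round(lat * 1000, 6),
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_population_summary(summary: PopulationSummary, path: str | Path) -> None:
    payload = {
        "n_units": summary.n_units,
        "wilcoxon_p": summary.wilcoxon_p,
        "n_units_in_z": summary.n_units_in_z,
        "counts": {f"{int(round(w * 1000))}ms": c for w, c in summary.counts.items()},
        "fractions": {f"{int(round(w * 1000))}ms": f
                      for w, f in summary.fractions.items()},
        "mean_z_trace": (None if summary.mean_z_trace is None
                         else [round(v, 9) for v in summary.mean_z_trace]),
        "z_trace_edges": [round(v, 9) for v in summary.z_trace_edges],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_session_metrics(metrics: Sequence[SessionMetrics], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "session_id": m.session_id,
                "n_active": m.n_active,
                "n_inactive": m.n_inactive,
                "poke_rate_per_min": m.poke_rate,
                "active_rate_per_min": m.active_rate,
                "mean_ipi_s": "" if m.mean_ipi is None else m.mean_ipi,
            }
            for m in metrics
        ]
    ).to_csv(path, sep="\t", index=False)


def write_bursts(bursts: dict[str, dict[float, BurstSet]], path: str | Path) -> None:
    rows = []
    for sid, by_threshold in bursts.items():
        for th, bs in by_threshold.items():
            for start, end, n in bs.bursts:
                rows.append({
                    "session_id": sid,
                    "gap_threshold_s": th,
                    "start_s": start,
                    "end_s": end,
                    "n_pokes": n,
                })
    pd.DataFrame(
        rows, columns=["session_id", "gap_threshold_s", "start_s", "end_s", "n_pokes"]
    ).to_csv(path, sep="\t", index=False)


def _require(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
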