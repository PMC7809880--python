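"""File formats: raw float32 traces with JSON sidecars, CSV event lists,
CSV histograms and JSON fit results.

Traces are stored as little-endian float32 arrays (``.dat``) next to a JSON
sidecar (``.json``) holding the sampling rate, voltage, filter cutoff and
provenance (scheme, seed) for synthetic data.  CSV import/export is provided
for interoperability; no vendor acquisition formats are read.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .detect import EventList
from .dwell import DwellTimeHistogram, ExponentialMixtureFit, StateStatistics
from .simulate import CurrentTrace

__all__ = ["write_trace", "read_trace", "trace_to_csv", "trace_from_csv",
           "write_events", "read_events", "write_histogram", "write_json",
           "state_statistics_to_dict", "fit_to_dict"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_trace(trace: CurrentTrace, path: str | Path) -> Path:
    """Write samples as little-endian float32 plus a JSON metadata sidecar."""
    path = Path(path).with_suffix(".dat")
    np.asarray(trace.samples, dtype="<f4").tofile(path)
    meta = {
        "sampling_rate": trace.sampling_rate,
        "voltage": trace.voltage,
        "filter_cutoff": trace.filter_cutoff,
        "n_samples": int(len(trace.samples)),
        "dtype": "<f4",
        **trace.meta,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def read_trace(path: str | Path) -> CurrentTrace:
    path = Path(path).with_suffix(".dat")
    meta = json.loads(_sidecar(path).read_text())
    samples = np.fromfile(path, dtype="<f4").astype(float)
    core = {k: meta.pop(k) for k in
            ("sampling_rate", "voltage", "filter_cutoff")}
    meta.pop("n_samples", None)
    meta.pop("dtype", None)
    return CurrentTrace(samples, core["sampling_rate"], core["voltage"],
                        core["filter_cutoff"], meta)


def trace_to_csv(trace: CurrentTrace, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": trace.times, "current_pA": trace.samples}
                 ).to_csv(path, index=False)
    _sidecar(path).write_text(json.dumps({
        "sampling_rate": trace.sampling_rate, "voltage": trace.voltage,
        "filter_cutoff": trace.filter_cutoff, **trace.meta}, indent=2))
    return path


def trace_from_csv(path: str | Path) -> CurrentTrace:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    return CurrentTrace(df["current_pA"].to_numpy(float),
                        meta.pop("sampling_rate"), meta.pop("voltage"),
                        meta.pop("filter_cutoff"), meta)


def write_events(events: EventList, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"state": events.states, "start_s": events.starts,
                  "duration_s": events.durations}).to_csv(path, index=False)
    _sidecar(path).write_text(json.dumps(events.meta, indent=2))
    return path


def read_events(path: str | Path) -> EventList:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = _sidecar(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return EventList(df["state"].tolist(), df["start_s"].to_numpy(float),
                     df["duration_s"].to_numpy(float), meta)


def write_histogram(hist: DwellTimeHistogram, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"edge_lo_s": hist.edges[:-1], "edge_hi_s": hist.edges[1:],
                  "count": hist.counts}).to_csv(path, index=False)
    return path


def fit_to_dict(fit: ExponentialMixtureFit) -> dict:
    return {
        "n_components": fit.n_components,
        "N": [float(a) for a in fit.amplitudes],
        "tau_s": [float(t) for t in fit.taus],
        "r2": fit.r2,
        "r2_adj": fit.r2_adj,
        "n_points": fit.n_points,
        "n_params": fit.n_params,
        "estimated_by_averaging": [bool(e) for e in fit.estimated],
        # the rare-state rule and the missed-events correction are
        # approximations, flagged for downstream consumers
        "approximate_corrections": True,
    }


def state_statistics_to_dict(stats: StateStatistics) -> dict:
    return {
        "states": stats.states,
        "P": {s: stats.probabilities[s] for s in stats.states},
        "tau_s": {s: stats.lifetimes[s] for s in stats.states},
        "N": {s: stats.counts[s] for s in stats.states},
        "f_per_s": {s: stats.frequencies[s] for s in stats.states},
        "tau_open_corrected_s": stats.tau_open_corrected,
    }


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default))
    return path
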