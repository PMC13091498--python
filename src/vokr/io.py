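"""Reading and writing traces, saccade events and protocol configs.

CSV is the canonical interchange format (columns ``time_s, eye, plane,
position_deg``); HDF5 bundles multi-phase recordings with the stimulus
phases stored as group attributes.  Round trips are lossless to well
below 1e-9 deg.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocess import EyeTrace
from .stimulus import Protocol, StimulusPhase

__all__ = [
    "read_traces", "write_traces", "read_traces_hdf5", "write_traces_hdf5",
    "write_saccades", "read_saccades", "config_hash",
]

CSV_COLUMNS = ["time_s", "eye", "plane", "position_deg"]


class SchemaError(ValueError):
    """Input file does not follow the expected trace schema."""


def write_traces(traces: dict[str, EyeTrace], path) -> None:
    """Write a set of traces to one tidy CSV."""
    frames = []
    for trace in traces.values():
        frames.append(pd.DataFrame({
            "time_s": trace.times,
            "eye": trace.eye,
            "plane": trace.plane,
            "position_deg": trace.positions,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces(path) -> dict[str, EyeTrace]:
    """Read traces from CSV; keys are ``"{eye}_{plane}"``."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    out: dict[str, EyeTrace] = {}
    for (eye, plane), g in df.groupby(["eye", "plane"], sort=False):
        g = g.sort_values("time_s")
        t = g["time_s"].to_numpy()
        if t.size < 2:
            raise SchemaError(f"trace {eye}/{plane} has fewer than 2 samples")
        dt = np.diff(t)
        if np.ptp(dt) > 1e-9:
            raise SchemaError(f"trace {eye}/{plane} is not uniformly sampled")
        out[f"{eye}_{plane}"] = EyeTrace(
            positions=g["position_deg"].to_numpy(),
            sample_rate=1.0 / float(dt[0]), plane=str(plane), eye=str(eye),
            t0=float(t[0]))
    return out


def write_traces_hdf5(traces: dict[str, EyeTrace], path,
                      protocol: Protocol | None = None) -> None:
    """Write traces (and optionally the protocol) to an HDF5 bundle."""
    with h5py.File(path, "w") as f:
        g = f.create_group("traces")
        for key, trace in traces.items():
            d = g.create_dataset(key, data=trace.positions)
            d.attrs["sample_rate"] = trace.sample_rate
            d.attrs["plane"] = trace.plane
            d.attrs["eye"] = trace.eye
            d.attrs["t0"] = trace.t0
        if protocol is not None:
            pg = f.create_group("protocol")
            pg.attrs["seed"] = protocol.seed
            pg.attrs["metadata"] = json.dumps(protocol.metadata)
            for i, phase in enumerate(protocol.phases):
                sub = pg.create_group(f"phase_{i:04d}")
                for k, v in phase.to_dict().items():
                    sub.attrs[k] = v


def read_traces_hdf5(path):
    """Read an HDF5 bundle; returns ``(traces, protocol_or_None)``."""
    traces: dict[str, EyeTrace] = {}
    protocol = None
    with h5py.File(path, "r") as f:
        for key, d in f["traces"].items():
            traces[key] = EyeTrace(
                positions=d[()], sample_rate=float(d.attrs["sample_rate"]),
                plane=str(d.attrs["plane"]), eye=str(d.attrs["eye"]),
                t0=float(d.attrs["t0"]))
        if "protocol" in f:
            pg = f["protocol"]
            phases = [
                StimulusPhase(**{k: (v.item() if hasattr(v, "item") else v)
                                 for k, v in pg[name].attrs.items()})
                for name in sorted(pg)
            ]
            protocol = Protocol(
                phases=phases, seed=int(pg.attrs["seed"]),
                metadata=json.loads(pg.attrs["metadata"]))
    return traces, protocol


def write_saccades(events, path) -> None:
    """Export saccade events as CSV (one row per event, all fields)."""
    rows = [dataclasses.asdict(ev) for ev in events]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_saccades(path) -> pd.DataFrame:
    return pd.read_csv(path)


def config_hash(obj) -> str:
    """Short stable hash of a configuration (dataclass or dict)."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
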