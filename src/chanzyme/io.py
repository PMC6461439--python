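"""File formats: TSV tables with JSON metadata sidecars.

Traces are stored as two-column TSV (`time_s`, `current_pA`) with a
`<name>.meta.json` sidecar carrying sampling rate, filter setting, units
and provenance; writing then reading a trace is bit-exact on the sample
values.  Idealized records, dwell tables, assay series and fit results
use the analogous plain-text conventions so every artifact is diffable.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AssaySeries, DwellTable, IdealizedRecord, Trace

__all__ = [
    "write_trace",
    "read_trace",
    "write_assay_series",
    "read_assay_series",
    "write_idealized",
    "read_idealized",
    "write_dwells",
    "read_dwells",
    "write_result_json",
    "sidecar_path",
]


def sidecar_path(path) -> Path:
    p = Path(path)
    return p.with_name(p.stem + ".meta.json")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_trace(trace: Trace, path) -> None:
    path = Path(path)
    # 17 significant digits round-trips every double exactly
    pd.DataFrame({"time_s": trace.times, "current_pA": trace.samples}).to_csv(
        path, sep="\t", index=False, float_format="%.17g")
    meta = {
        "sampling_hz": trace.sampling_rate,
        "filter_hz": trace.filter_cutoff,
        "units": {"time": "s", "current": "pA"},
        "provenance": _jsonable(trace.metadata),
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_trace(path) -> Trace:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "time_s" not in df.columns or "current_pA" not in df.columns:
        raise ValueError("trace TSV must have columns time_s and current_pA")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("time column must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > 1e-6 * dt[0]:
            raise ValueError("irregular time steps: trace must be uniformly sampled")
    side = sidecar_path(path)
    filter_hz = None
    metadata: dict = {}
    if side.exists():
        meta = json.loads(side.read_text())
        sampling = meta.get("sampling_hz")
        filter_hz = meta.get("filter_hz")
        metadata = meta.get("provenance", {}) or {}
        if sampling is None:
            sampling = _infer_sampling(t, path)
    else:
        warnings.warn(f"missing sidecar {side}; defaults assumed")
        sampling = _infer_sampling(t, path)
    return Trace(df["current_pA"].to_numpy(dtype=float), float(sampling),
                 filter_hz, metadata)


def _infer_sampling(t: np.ndarray, path) -> float:
    if t.size < 2:
        raise ValueError(f"{path}: cannot infer sampling rate from a single sample")
    rate = 1.0 / float(np.mean(np.diff(t)))
    warnings.warn(f"{path}: sampling rate inferred from time column ({rate:g} Hz)")
    return rate


def write_assay_series(series: AssaySeries, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{series.x_label}\t{series.y_label}\n")
        for xi, yi in zip(series.x, series.y):
            fh.write(f"{float(xi)!r}\t{float(yi)!r}\n")
    meta = {"x_label": series.x_label, "y_label": series.y_label,
            "normalized": series.normalized, "provenance": _jsonable(series.metadata)}
    sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_assay_series(path) -> AssaySeries:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError("assay TSV needs a condition column and a value column")
    x_label, y_label = df.columns[0], df.columns[-1]
    side = sidecar_path(path)
    normalized = False
    metadata: dict = {}
    if side.exists():
        meta = json.loads(side.read_text())
        normalized = bool(meta.get("normalized", False))
        metadata = meta.get("provenance", {}) or {}
    return AssaySeries(df[x_label].to_numpy(dtype=float),
                       df[y_label].to_numpy(dtype=float),
                       x_label=x_label, y_label=y_label,
                       normalized=normalized, metadata=metadata)


def write_idealized(record: IdealizedRecord, path) -> None:
    path = Path(path)
    starts = record.start_times
    with open(path, "w") as fh:
        fh.write("start_s\tduration_s\tlevel\n")
        for s, d, l in zip(starts, record.durations, record.levels):
            fh.write(f"{float(s)!r}\t{float(d)!r}\t{int(l)}\n")
    meta = {"dead_time_s": record.dead_time, "n_events": record.n_events}
    sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_idealized(path) -> IdealizedRecord:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    dead = None
    side = sidecar_path(path)
    if side.exists():
        dead = json.loads(side.read_text()).get("dead_time_s")
    return IdealizedRecord(df["level"].to_numpy(dtype=int),
                           df["duration_s"].to_numpy(dtype=float),
                           dead_time=dead)


def write_dwells(table: DwellTable, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("level\tdwell_s\n")
        for lvl in sorted(table.dwells):
            for d in table.dwells[lvl]:
                fh.write(f"{int(lvl)}\t{float(d)!r}\n")
    meta = {"occupancy_s": {str(k): v for k, v in table.occupancy.items()},
            "dead_time_s": table.dead_time}
    sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_dwells(path) -> DwellTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    dwells = {int(lvl): grp["dwell_s"].to_numpy(dtype=float)
              for lvl, grp in df.groupby("level")}
    side = sidecar_path(path)
    dead = None
    if side.exists():
        meta = json.loads(side.read_text())
        occupancy = {int(k): float(v) for k, v in (meta.get("occupancy_s") or {}).items()}
        dead = meta.get("dead_time_s")
    else:
        occupancy = {}
    if not occupancy:
        occupancy = {lvl: float(v.sum()) for lvl, v in dwells.items()}
    return DwellTable(dwells=dwells, occupancy=occupancy, dead_time=dead)


def write_result_json(result, path) -> None:
    """Serialize a fit-result dataclass (or mapping) to JSON."""
    Path(path).write_text(json.dumps(_jsonable(result), indent=1))
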