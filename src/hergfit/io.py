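"""CSV/JSON interchange for traces, datasets and fit results.

The trace dialect is a long-format CSV with columns ``sweep_id``,
``time_ms``, ``voltage_mV``, ``current_uA`` (UTF-8, "." decimal
separator).  Within a sweep, time must be strictly increasing and
uniformly spaced; violations raise errors naming the offending sweep.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import CurrentTrace, VoltageProtocol

__all__ = [
    "TRACE_COLUMNS",
    "read_trace_csv",
    "write_trace_csv",
    "write_fit_json",
    "load_protocol_json",
]

TRACE_COLUMNS = ("sweep_id", "time_ms", "voltage_mV", "current_uA")


def read_trace_csv(path) -> dict:
    """Read a trace CSV into an ordered {sweep_id: CurrentTrace} mapping."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"sweep_id": str})
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty trace file") from None
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if len(df) == 0:
        raise ValueError(f"{path}: trace file has no rows")

    traces: dict = {}
    for sweep_id, grp in df.groupby("sweep_id", sort=False):
        t = grp["time_ms"].to_numpy(float)
        dt = np.diff(t)
        if len(t) >= 2:
            if np.any(dt <= 0):
                raise ValueError(f"{path}: sweep {sweep_id!r} has non-increasing time")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError(f"{path}: sweep {sweep_id!r} has non-uniform sampling")
        traces[str(sweep_id)] = CurrentTrace(
            time=t,
            command_voltage=grp["voltage_mV"].to_numpy(float),
            current=grp["current_uA"].to_numpy(float),
            metadata={"sweep_id": str(sweep_id), "source": str(path)},
        )
    return traces


def write_trace_csv(traces, path) -> None:
    """Write CurrentTrace objects (list or {id: trace} mapping) as a trace CSV.

    Floats are written with 9 significant digits, making write -> read a
    lossless round trip at that precision.
    """
    if isinstance(traces, CurrentTrace):
        traces = [traces]
    if isinstance(traces, dict):
        items = list(traces.items())
    else:
        items = [
            (tr.metadata.get("sweep_id", f"sweep{idx:03d}"), tr) for idx, tr in enumerate(traces)
        ]
    frames = []
    for sweep_id, tr in items:
        frames.append(
            pd.DataFrame(
                {
                    "sweep_id": sweep_id,
                    "time_ms": tr.time,
                    "voltage_mV": tr.command_voltage,
                    "current_uA": tr.current,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.9g")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, float) and not np.isfinite(x):
        return None
    return x


def write_fit_json(path, model_tag: str, params: dict, fit_result, extra: dict | None = None):
    """Serialize a fit (parameter record + FitResult summary) to JSON."""
    payload = fit_result.to_dict(params=params)
    payload["model_tag"] = model_tag
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(_jsonable(payload), fh, indent=2)


def load_protocol_json(path) -> VoltageProtocol:
    with open(path) as fh:
        return VoltageProtocol.from_dict(json.load(fh))
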