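"""File-format helpers: CSV traces/tables, multi-page TIFF stacks, YAML
configuration, JSON truth sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml


def write_pulse_csv(timestamps: np.ndarray, path) -> None:
    """One column ``t_s``, header row, 6 decimal places."""
    df = pd.DataFrame({"t_s": np.asarray(timestamps, dtype=float)})
    df.to_csv(path, index=False, float_format="%.6f")


def read_pulse_csv(path) -> np.ndarray:
    return pd.read_csv(path)["t_s"].to_numpy()


def write_traces_csv(traces: np.ndarray, path, unit_ids=None) -> None:
    """Unit-by-frame matrix with a ``unit_id`` index column."""
    traces = np.atleast_2d(traces)
    idx = unit_ids if unit_ids is not None else range(traces.shape[0])
    pd.DataFrame(traces, index=pd.Index(idx, name="unit_id")).to_csv(path)


def read_traces_csv(path) -> tuple[np.ndarray, list]:
    df = pd.read_csv(path, index_col="unit_id")
    return df.to_numpy(), list(df.index)


def write_stack_tiff(stack: np.ndarray, path) -> None:
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32))


def read_stack_tiff(path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_mask_tiff(mask: np.ndarray, path) -> None:
    tifffile.imwrite(str(path), np.asarray(mask, dtype=np.int32))


def read_trace_table(path) -> tuple[np.ndarray, float]:
    """CSV of (time_s, current_pA) -> (samples, sampling rate)."""
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ValueError("trace needs at least 2 samples")
    rate = 1.0 / float(np.median(np.diff(t)))
    return df["current_pA"].to_numpy(), rate


def write_trace_table(samples: np.ndarray, sampling_rate: float, path) -> None:
    t = np.arange(len(samples)) / sampling_rate
    pd.DataFrame({"time_s": t, "current_pA": samples}).to_csv(path, index=False)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_json(obj, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, default=default))
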