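"""Plain-text readers and writers for waveforms, annotations and tables.

Waveforms travel as two-column text (time_s, amplitude) with the sampling
rate echoed in a comment header; multi-channel records are CSV files with
named columns, from which the pulsatile channel (name containing PLETH or
PPG, case-insensitive) is selected.  Tables are CSV, reports and manifests
JSON — everything is diffable and binary-free.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Waveform

__all__ = [
    "write_two_column",
    "read_two_column",
    "read_record",
    "write_onsets",
    "read_onsets",
    "write_feature_table",
    "read_feature_table",
    "write_markers",
    "write_report",
]

log = logging.getLogger("ppgarr")

_PULSATILE_CHANNEL = re.compile(r"(pleth|ppg)", re.IGNORECASE)


def write_two_column(path: str | Path, samples: np.ndarray, fs: float, header: str = "") -> None:
    samples = np.asarray(samples, dtype=float)
    t = np.arange(samples.size) / fs
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write(f"# fs_hz={fs:.10g}\n")
        for ti, xi in zip(t, samples):
            fh.write(f"{ti:.6f}\t{xi:.9g}\n")


def read_two_column(path: str | Path) -> Waveform:
    fs = None
    times, values = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.search(r"fs_hz=([\d.eE+-]+)", line)
                if m:
                    fs = float(m.group(1))
                continue
            parts = line.replace(",", "\t").split()
            times.append(float(parts[0]))
            values.append(float(parts[1]))
    if len(values) < 2:
        raise ValueError(f"{path}: fewer than 2 samples")
    values_arr = np.array(values)
    if fs is None:
        dt = np.median(np.diff(times))
        if dt <= 0:
            raise ValueError(f"{path}: cannot infer sampling rate")
        fs = 1.0 / dt
    # linear interpolation over any non-finite runs, logged
    bad = ~np.isfinite(values_arr)
    if bad.any():
        log.warning("%s: interpolating %d missing samples", path, int(bad.sum()))
        idx = np.arange(values_arr.size)
        values_arr[bad] = np.interp(idx[bad], idx[~bad], values_arr[~bad])
    return Waveform(values_arr, fs)


def read_record(path: str | Path, fmt: str = "auto") -> Waveform:
    """Read a waveform record.

    ``two-column-text`` is the native format; ``csv`` denotes a
    multi-channel table with named columns, from which the PLETH/PPG channel
    is selected (a ``time_s`` column, when present, sets the sampling rate).
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "csv" if path.suffix.lower() == ".csv" else "two-column-text"
    if fmt == "two-column-text":
        return read_two_column(path)
    if fmt == "csv":
        df = pd.read_csv(path, comment="#")
        channels = [c for c in df.columns if _PULSATILE_CHANNEL.search(c)]
        if not channels:
            raise ValueError(f"{path}: no pulsatile (PLETH/PPG) channel found")
        values = df[channels[0]].to_numpy(dtype=float)
        time_cols = [c for c in df.columns if c.lower() in ("time_s", "time", "t")]
        if time_cols:
            dt = float(np.median(np.diff(df[time_cols[0]].to_numpy(dtype=float))))
            fs = 1.0 / dt
        else:
            raise ValueError(f"{path}: csv record needs a time column to infer fs")
        bad = ~np.isfinite(values)
        if bad.any():
            log.warning("%s: interpolating %d missing samples", path, int(bad.sum()))
            idx = np.arange(values.size)
            values[bad] = np.interp(idx[bad], idx[~bad], values[~bad])
        return Waveform(values, fs)
    raise ValueError(f"unknown record format {fmt!r}")


def write_onsets(path: str | Path, onsets_s: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("onset_s\n")
        for t in np.asarray(onsets_s, dtype=float):
            fh.write(f"{t:.6f}\n")


def read_onsets(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    return df["onset_s"].to_numpy(dtype=float)


def _meta_header(meta: dict | None) -> str:
    if not meta:
        return ""
    fields = " ".join(f"{k}={v}" for k, v in sorted(meta.items()))
    return f"# {fields}\n"


def write_feature_table(path: str | Path, table: pd.DataFrame, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_header(meta))
        table.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_markers(path: str | Path, rows: list[dict], meta: dict | None = None) -> None:
    cols = [
        "record_id",
        "segment_start_s",
        "pulse_index",
        "valley_idx",
        "peak_idx",
        "notch_start_idx",
        "notch_end_idx",
        "valid_flag",
    ]
    df = pd.DataFrame(rows, columns=cols)
    with open(path, "w") as fh:
        fh.write(_meta_header(meta))
        df.to_csv(fh, index=False, lineterminator="\n")


def write_report(path: str | Path, report: dict, meta: dict | None = None) -> None:
    payload = dict(report)
    if meta:
        payload["meta"] = meta
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
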