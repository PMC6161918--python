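"""Interchange CSV dialects of the pipeline.

Sample tables: participant, trial, time_ms (int, trial-relative, constant
4 ms step at 250 Hz), lx_px, ly_px, rx_px, ry_px, l_pupil_mm, r_pupil_mm.
Empty cells mean invalid samples and round-trip as NaN, never 0. Pixel
coordinates have their origin at the top-left of the screen with the
center at (960, 540); y grows downward.

Event tables use the schema shared by the simulator's ground truth and the
detector output, so recovery reports can diff two files directly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import SAMPLE_COLUMNS


class SampleTableError(ValueError):
    """Malformed sample table; the message names the violation and row."""


_FLOAT_COLUMNS = ["lx_px", "ly_px", "rx_px", "ry_px",
                  "l_pupil_mm", "r_pupil_mm"]


def read_samples(path, expected_step_ms: float = 4.0) -> pd.DataFrame:
    """Read and validate a sample table.

    Checks the header, numeric parsability of every cell (reported with
    1-based data line numbers), and the time contract: strictly increasing
    time_ms per trial with the constant expected step.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SAMPLE_COLUMNS if c not in raw.columns]
    if missing:
        raise SampleTableError(f"missing columns: {missing}")
    out = pd.DataFrame(index=raw.index)
    for col in ("participant", "trial", "time_ms"):
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise SampleTableError(
                f"column {col}: non-numeric value at line {line}")
        out[col] = vals.astype(np.int64)
    for col in _FLOAT_COLUMNS:
        vals = pd.to_numeric(raw[col].replace("", np.nan), errors="coerce")
        bad = vals.isna() & (raw[col] != "")
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise SampleTableError(
                f"column {col}: unparsable value {raw[col][bad.idxmax()]!r} "
                f"at line {line}")
        out[col] = vals
    for (pid, tid), grp in out.groupby(["participant", "trial"], sort=False):
        t = grp["time_ms"].to_numpy()
        if t.size < 2:
            continue
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise SampleTableError(
                f"participant {pid} trial {tid}: time_ms not strictly "
                "increasing")
        if np.any(steps != round(expected_step_ms)):
            i = int(np.flatnonzero(steps != round(expected_step_ms))[0])
            raise SampleTableError(
                f"participant {pid} trial {tid}: time step {steps[i]} ms at "
                f"sample {i + 1} (expected {expected_step_ms} ms)")
    return out[SAMPLE_COLUMNS]


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, index=False, float_format="%.6f")


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"type", "onset_ms", "offset_ms"}
    missing = required - set(df.columns)
    if missing:
        raise SampleTableError(f"events table missing columns: {sorted(missing)}")
    return df


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("participant", "trial", "condition", "block")
               if c not in df.columns]
    if missing:
        raise SampleTableError(f"trial table missing columns: {missing}")
    return df


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def import_tracker_export(path, column_map: dict, sep: str = "\t",
                          time_unit: str = "ms") -> pd.DataFrame:
    """Shim for tab-separated eye-tracker exports.

    ``column_map`` maps the export's column names to the sample-table
    dialect (e.g. ``{"Time": "time_ms", "L POR X [px]": "lx_px", ...}``).
    ``time_unit`` may be "ms" or "us".
    """
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in column_map if c not in df.columns]
    if missing:
        raise SampleTableError(f"export missing mapped columns: {missing}")
    out = df[list(column_map)].rename(columns=column_map)
    if time_unit == "us":
        out["time_ms"] = (out["time_ms"] / 1000.0).round().astype(np.int64)
    for col in ("participant", "trial"):
        if col not in out.columns:
            out[col] = 0
    for col in SAMPLE_COLUMNS:
        if col not in out.columns:
            raise SampleTableError(f"column_map does not produce {col}")
    return out[SAMPLE_COLUMNS]
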