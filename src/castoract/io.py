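"""CSV/JSON interchange for traces, segment tables, features and reports.

Trace CSVs carry one row per 8-Hz acceleration sample (``time_s, surge_g,
sway_g, heave_g``) with the 2-Hz pressure channel interleaved on every
fourth row (``pressure_mB``, blank elsewhere). Values round-trip to six
decimal places.
"""

from __future__ import annotations

import os
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES
from .simulate import AccelTrace, LabeledSegment

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_segments_csv",
    "read_segments_csv",
    "segments_from_table",
    "write_features_csv",
    "read_features_csv",
]

_TRACE_COLUMNS = ("time_s", "surge_g", "sway_g", "heave_g")


def write_trace_csv(trace: AccelTrace, path: str) -> None:
    """Write a trace (and its pressure channel, if any) to CSV."""
    df = pd.DataFrame(
        {
            "time_s": trace.times,
            "surge_g": trace.surge,
            "sway_g": trace.sway,
            "heave_g": trace.heave,
        }
    )
    if trace.pressure is not None:
        ratio = int(round(trace.sample_rate_accel / trace.sample_rate_pressure))
        pressure = np.full(len(df), np.nan)
        n = min(len(trace.pressure), (len(df) + ratio - 1) // ratio)
        pressure[: n * ratio: ratio] = trace.pressure[:n]
        df["pressure_mB"] = pressure
    df.to_csv(path, index=False, float_format="%.6f")


def read_trace_csv(
    path: str,
    sample_rate_accel: float = 8.0,
    sample_rate_pressure: float = 2.0,
) -> AccelTrace:
    """Read a trace CSV written by :func:`write_trace_csv`."""
    if os.path.getsize(path) == 0:
        raise ValueError(f"empty trace file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace CSV {path} is missing columns: {missing}")
    if len(df) == 0:
        raise ValueError(f"trace CSV {path} has no samples")
    pressure = None
    if "pressure_mB" in df.columns:
        pressure = df["pressure_mB"].dropna().to_numpy()
        if pressure.size == 0:
            pressure = None
    return AccelTrace(
        df["surge_g"].to_numpy(),
        df["sway_g"].to_numpy(),
        df["heave_g"].to_numpy(),
        pressure=pressure,
        sample_rate_accel=sample_rate_accel,
        sample_rate_pressure=sample_rate_pressure,
        start_time_s=float(df["time_s"].iloc[0]),
    )


def write_segments_csv(segments: Sequence[LabeledSegment], path: str) -> None:
    """Write the segment table (segment_id, label, start_s, end_s)."""
    pd.DataFrame(
        {
            "segment_id": [s.segment_id for s in segments],
            "label": [s.label for s in segments],
            "start_s": [s.start_s for s in segments],
            "end_s": [s.end_s for s in segments],
        }
    ).to_csv(path, index=False, float_format="%.6f")


def read_segments_csv(path: str) -> pd.DataFrame:
    """Read a segment table; returns a DataFrame of bounds and labels."""
    if os.path.getsize(path) == 0:
        raise ValueError(f"empty segment file: {path}")
    df = pd.read_csv(path)
    required = ("segment_id", "label", "start_s", "end_s")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"segment CSV {path} is missing columns: {missing}")
    return df


def segments_from_table(
    trace: AccelTrace, table: pd.DataFrame
) -> list[LabeledSegment]:
    """Materialise labelled segments by slicing a trace along a segment table."""
    out = []
    for row in table.itertuples(index=False):
        out.append(
            LabeledSegment(
                segment_id=str(row.segment_id),
                label=str(row.label),
                start_s=float(row.start_s),
                end_s=float(row.end_s),
                trace=trace.slice(float(row.start_s), float(row.end_s)),
            )
        )
    return out


def write_features_csv(table: pd.DataFrame, path: str) -> None:
    """Write a feature table produced by :func:`castoract.features.features_table`."""
    table.to_csv(path, index=False, float_format="%.6f")


def read_features_csv(path: str) -> pd.DataFrame:
    """Read a feature table; validates the 8 feature columns are present."""
    if os.path.getsize(path) == 0:
        raise ValueError(f"empty feature file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in ("label", *FEATURE_NAMES) if c not in df.columns]
    if missing:
        raise ValueError(f"feature CSV {path} is missing columns: {missing}")
    return df
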