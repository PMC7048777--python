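"""Readers and writers for traces, event tables and ground truth.

Traces travel as 2-column delimited text (``time_s,value``) with an optional
sidecar JSON (``<path>.json``) declaring units, sampling rate and modality;
uniform sampling is verified on read.  Event tables and ground truth are
TSV.  All writers embed the package version so outputs are traceable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .events import EventTable, Trace
from .trace_sim import GroundTruth

__all__ = [
    "read_trace",
    "write_trace",
    "read_event_table",
    "write_event_table",
    "read_ground_truth",
    "write_ground_truth",
]

_UNIT_MODALITY = {"pA": "voltage_clamp", "mV": "current_clamp"}


def read_trace(
    path: str | Path,
    units: str | None = None,
    fs_hz: float | None = None,
    uniformity_tol_s: float = 1e-9,
) -> Trace:
    """Read a 2-column (time_s, value) delimited trace file.

    ``units`` may come from the sidecar JSON, the argument, or default to pA.
    The sampling rate is inferred from the time column unless given; the time
    column must be uniform to within ``uniformity_tol_s`` (the first
    offending row is named otherwise).
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ("," if "," in first else r"\s+")
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns, found {df.shape[1]}")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)

    sidecar = path.with_name(path.name + ".json")
    meta = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    units = units or meta.get("units") or "pA"
    fs = fs_hz or meta.get("fs_hz")
    if fs is None:
        if t.size < 2:
            raise ValueError(f"{path}: cannot infer fs from a single row")
        fs = 1.0 / float(np.median(np.diff(t)))
    dt = 1.0 / fs
    expected = t[0] + dt * np.arange(t.size)
    dev = np.abs(t - expected)
    if dev.max() > uniformity_tol_s:
        row = int(np.argmax(dev > uniformity_tol_s))
        raise ValueError(
            f"{path}: non-uniform sampling at row {row} "
            f"(time {t[row]:.9f}, expected {expected[row]:.9f})"
        )
    modality = meta.get("modality") or _UNIT_MODALITY.get(units, "voltage_clamp")
    return Trace(samples=v, fs_hz=float(fs), units=units, modality=modality)


def write_trace(path: str | Path, trace: Trace, float_fmt: str = "%.17g") -> None:
    """Write a trace as CSV plus a sidecar JSON with units/fs/modality."""
    path = Path(path)
    t = np.arange(trace.samples.size) / trace.fs_hz
    pd.DataFrame({"time_s": t, "value": trace.samples}).to_csv(
        path, index=False, float_format=float_fmt
    )
    meta = {
        "units": trace.units,
        "fs_hz": trace.fs_hz,
        "modality": trace.modality,
        "version": __version__,
    }
    path.with_name(path.name + ".json").write_text(json.dumps(meta, indent=2))


def write_event_table(path: str | Path, events: EventTable) -> None:
    events.to_frame().to_csv(path, sep="\t", index=False)


def read_event_table(path: str | Path) -> EventTable:
    df = pd.read_csv(path, sep="\t")
    return EventTable(
        event_time_s=df["event_time_s"].to_numpy(dtype=float),
        amplitude_pa=df["amplitude_pa"].to_numpy(dtype=float),
    )


def write_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    pd.DataFrame(
        {"event_time_s": truth.event_times_s, "amplitude_pa": truth.event_amps_pa}
    ).to_csv(path, sep="\t", index=False)


def read_ground_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t")
    return GroundTruth(
        event_times_s=df["event_time_s"].to_numpy(dtype=float),
        event_amps_pa=df["amplitude_pa"].to_numpy(dtype=float),
    )
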