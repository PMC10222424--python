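"""Signal and recording file I/O.

The interchange format is a two-column CSV with header ``time_s,value``,
UTF-8, '.' decimal separator.  Timestamps must be uniform to 1e-6 s.
Simulation recordings export as a wide CSV (time plus one column per probe
trace) with a JSON sidecar of per-region activation times.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cardiac_model import FieldRecording
from .signals import ECGSignal

__all__ = ["read_signal", "write_signal", "write_recording", "read_recording_traces"]

_TIME_TOL_S = 1e-6


def write_signal(signal: ECGSignal, path: str | Path) -> None:
    """Write a ``time_s,value`` CSV.

    Values are written at full double precision (%.17g) so they round-trip
    exactly; timestamps at %.9g, far inside the 1e-6 s uniformity tolerance.
    """
    path = Path(path)
    t = np.char.mod("%.9g", signal.times)
    v = np.char.mod("%.17g", signal.samples)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("time_s,value\n")
        fh.write("\n".join(np.char.add(np.char.add(t, ","), v)))
        fh.write("\n")


def read_signal(path: str | Path, channel: str = "") -> ECGSignal:
    """Read a ``time_s,value`` CSV back into an :class:`ECGSignal`.

    Raises on a malformed header or non-uniform timestamps.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["time_s", "value"]:
        raise ValueError(
            f"{path}: expected header 'time_s,value', got {','.join(df.columns)}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = np.diff(t)
    T = float(np.median(dt))
    if T <= 0 or np.any(np.abs(dt - T) > _TIME_TOL_S):
        raise ValueError(f"{path}: non-uniform or non-increasing timestamps "
                         f"(tolerance {_TIME_TOL_S} s)")
    return ECGSignal(samples=df["value"].to_numpy(dtype=float), T=T,
                     channel=channel or path.stem, t0=float(t[0]))


def write_recording(recording: FieldRecording, traces_path: str | Path,
                    sidecar_path: str | Path | None = None) -> None:
    """Export all probe traces (wide CSV) plus activation times (JSON)."""
    traces_path = Path(traces_path)
    cols = {"time_s": recording.times}
    for name, trace in recording.probe_traces.items():
        cols[name] = trace
    pd.DataFrame(cols).to_csv(traces_path, index=False, float_format="%.9g")
    if sidecar_path is not None:
        payload = {
            "activation_times_s": {r.value: t for r, t in recording.activation_times.items()},
            "cycle_seconds": recording.cycle_seconds,
            "dt_sim": recording.dt,
            "warnings": recording.warnings,
        }
        Path(sidecar_path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_recording_traces(path: str | Path) -> dict[str, ECGSignal]:
    """Read a wide recording CSV into one :class:`ECGSignal` per probe."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns[0] != "time_s":
        raise ValueError(f"{path}: first column must be time_s")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    T = float(np.median(dt))
    if np.any(np.abs(dt - T) > _TIME_TOL_S):
        raise ValueError(f"{path}: non-uniform timestamps")
    return {c: ECGSignal(samples=df[c].to_numpy(dtype=float), T=T, channel=c,
                         provenance="simulated", t0=float(t[0]))
            for c in df.columns[1:]}
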