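"""Plain-text file formats for traces, events, matrices and reports.

Traces: CSV with header ``time_s,f465_v,f405_v``.
Events: CSV with header ``onset_s,label``.
Processed traces: CSV ``time_s,dff`` plus a JSON fit report.
Z-score matrices: CSV, one row per event, columns = relative-time samples.
Ground truth and run reports: JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from fiberphot.alignment import EventSeries, KNOWN_LABELS, ZScoreMatrix
from fiberphot.preprocess import PhotometryTrace, ProcessedTrace

__all__ = [
    "read_photometry_csv",
    "write_photometry_csv",
    "read_events_csv",
    "write_events_csv",
    "write_processed",
    "write_zscore_matrix",
    "write_json",
    "file_sha256",
]

log = logging.getLogger("fiberphot")

TRACE_COLUMNS = ["time_s", "f465_v", "f405_v"]
EVENT_COLUMNS = ["onset_s", "label"]


def read_photometry_csv(path: str | Path,
                        animal_id: str = "",
                        session_id: str = "") -> PhotometryTrace:
    """Load and validate a two-channel trace CSV.

    The sampling rate is inferred from the median time step; the
    ``PhotometryTrace`` constructor enforces uniform, strictly
    increasing time and finite samples.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if df[TRACE_COLUMNS].isna().any().any():
        raise ValueError(f"{path}: NaN values in trace columns")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError(f"{path}: time_s must be strictly increasing")
    rate = 1.0 / float(np.median(dt))
    return PhotometryTrace(
        time_s=t,
        f465=df["f465_v"].to_numpy(dtype=float),
        f405=df["f405_v"].to_numpy(dtype=float),
        rate_hz=rate,
        animal_id=animal_id,
        session_id=session_id,
    )


def write_photometry_csv(trace: PhotometryTrace, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({
        "time_s": trace.time_s,
        "f465_v": trace.f465,
        "f405_v": trace.f405,
    }).to_csv(path, index=False, float_format="%.17g")
    return path


def read_events_csv(path: str | Path,
                    animal_id: str = "",
                    session_id: str = "") -> EventSeries:
    """Load behavioral events; sort if needed, flag unknown labels."""
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if df.empty:
        raise ValueError(f"{path}: no events")
    if df["onset_s"].isna().any():
        raise ValueError(f"{path}: NaN onset")
    if not df["onset_s"].is_monotonic_increasing:
        log.warning("%s: onsets out of order, sorting", path)
        df = df.sort_values("onset_s")
    unknown = set(df["label"].astype(str)) - KNOWN_LABELS
    if unknown:
        log.warning("%s: unrecognized event label(s) %s", path, sorted(unknown))
    return EventSeries(
        df["onset_s"].to_numpy(dtype=float),
        df["label"].astype(str).to_numpy(dtype=object),
        animal_id=animal_id,
        session_id=session_id,
    )


def write_events_csv(events: EventSeries, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"onset_s": events.onsets, "label": events.labels}).to_csv(
        path, index=False, float_format="%.17g")
    return path


def write_processed(proc: ProcessedTrace, csv_path: str | Path,
                    fit_path: str | Path | None = None) -> Path:
    """Write ΔF/F0 CSV and a JSON report of the isosbestic fit."""
    csv_path = Path(csv_path)
    pd.DataFrame({"time_s": proc.time_s, "dff": proc.dff}).to_csv(
        csv_path, index=False, float_format="%.17g")
    if fit_path is not None:
        write_json({
            "slope": proc.fit.slope,
            "intercept": proc.fit.intercept,
            "sse": proc.fit.sse,
            "filter_cutoff_hz": proc.filter_cutoff_hz,
            "rate_hz": proc.rate_hz,
            "animal_id": proc.animal_id,
            "session_id": proc.session_id,
        }, fit_path)
    return csv_path


def write_zscore_matrix(z: ZScoreMatrix, path: str | Path) -> Path:
    """One row per event; columns are relative-time samples in seconds."""
    path = Path(path)
    df = pd.DataFrame(z.values, columns=[f"{t:.6f}" for t in z.time_rel_s])
    df.insert(0, "onset_s", z.onsets)
    df.insert(1, "label", z.labels)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")
    return path


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
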