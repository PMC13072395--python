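"""Readers and writers for the plain-text interchange formats.

Trace CSV: one header line, columns ``time_s,value`` (or a value-only
column with the sampling rate supplied by the caller).  Event-catalog CSV:
one row per event with times at 1e-4 s resolution (sample-accurate at
10 kHz).  Spectrogram CSV: header row of frequencies, first column of time
offsets.  Axon Binary Format (ABF) reading is feature-gated behind the
optional ``pyabf`` dependency.

Every writer/reader pair round-trips valid data exactly at the stated
resolution.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .ripples import EventCatalog, SwrEvent
from .spectral import SpectrogramGrid
from .trace import RecordingMeta, TimeSeriesTrace

__all__ = [
    "read_trace",
    "write_trace",
    "write_event_catalog",
    "read_event_catalog",
    "write_spectrogram",
    "read_spectrogram",
    "write_measurements",
    "read_measurements",
]

_UNIFORMITY_TOL = 1e-6  # 1 ppm relative deviation of sample intervals

CATALOG_COLUMNS = (
    "recording_id",
    "onset_s",
    "offset_s",
    "duration_ms",
    "amplitude",
    "peak_time_s",
    "peak_envelope",
)


def read_trace(
    path: str | Path,
    format: str = "csv",
    fs: float | None = None,
    units: str = "",
    channel_id: str = "",
) -> TimeSeriesTrace:
    """Read a trace from CSV (canonical) or ABF (optional).

    CSV dialect: one header line, columns ``time_s,value``; the sampling
    rate is inferred as the reciprocal of the median sample interval and
    the time column must be uniform to 1 ppm.  A value-only file needs
    ``fs`` supplied.  ABF requires the optional ``pyabf`` package.
    """
    path = Path(path)
    if format == "abf":
        return _read_abf(path, channel_id)
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - report as a format error
        raise ValueError(f"unreadable trace file {path}: {exc}") from exc
    cols = [c.strip() for c in df.columns]
    df.columns = cols
    if "value" not in cols:
        raise ValueError(f"{path}: expected a 'value' column, found {cols}")
    values = df["value"].to_numpy(dtype=float)
    if "time_s" in cols and len(df) >= 2:
        t = df["time_s"].to_numpy(dtype=float)
        dt = np.diff(t)
        med = float(np.median(dt))
        if med <= 0:
            raise ValueError(f"{path}: non-increasing time column")
        rel = np.abs(dt - med) / med
        bad = np.flatnonzero(rel > _UNIFORMITY_TOL)
        if bad.size:
            raise ValueError(
                f"{path}: non-uniform sampling at row {int(bad[0]) + 1} "
                f"(interval {dt[bad[0]]:.6g} s vs median {med:.6g} s)"
            )
        inferred = 1.0 / med
        t0 = float(t[0])
    else:
        if fs is None:
            raise ValueError(f"{path}: value-only file requires an explicit fs")
        inferred, t0 = float(fs), 0.0
    return TimeSeriesTrace(values, fs if fs is not None else inferred, t0=t0,
                           units=units, channel_id=channel_id or path.stem)


def _read_abf(path: Path, channel_id: str) -> TimeSeriesTrace:
    try:
        import pyabf  # type: ignore[import-not-found]
    except ImportError as exc:
        raise ImportError(
            "ABF reading requires the optional 'pyabf' dependency "
            "(pip install slicephys[abf]); CSV is the canonical format"
        ) from exc
    abf = pyabf.ABF(str(path))
    abf.setSweep(0)
    return TimeSeriesTrace(
        np.asarray(abf.sweepY, dtype=float), float(abf.dataRate),
        units=abf.sweepUnitsY, channel_id=channel_id or path.stem,
    )


def write_trace(trace: TimeSeriesTrace, path: str | Path) -> None:
    """Write a trace as ``time_s,value`` CSV."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "value"])
        for t, v in zip(trace.times, trace.samples):
            w.writerow([f"{t:.6f}", f"{v:.17g}"])


def write_event_catalog(catalog: EventCatalog, path: str | Path) -> None:
    """Write a catalog as CSV; times at 1e-4 s resolution.

    The catalog invariants (sorted, disjoint events) are enforced by the
    :class:`EventCatalog` constructor, so any violation raises before a
    file is touched.
    """
    # re-validate: constructing a fresh catalog re-runs the invariants
    EventCatalog(catalog.recording_id, list(catalog.events), catalog.recording_duration_s)
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CATALOG_COLUMNS)
        for e in catalog.events:
            w.writerow(
                [
                    catalog.recording_id,
                    f"{e.onset_s:.4f}",
                    f"{e.offset_s:.4f}",
                    f"{e.duration_ms:.4f}",
                    f"{e.amplitude:.17g}",
                    f"{e.peak_time_s:.4f}",
                    f"{e.peak_envelope:.17g}",
                ]
            )


def read_event_catalog(
    path: str | Path, recording_duration_s: float | None = None
) -> EventCatalog:
    """Read a catalog CSV written by :func:`write_event_catalog`.

    If ``recording_duration_s`` is not given, the last event offset is
    used as a lower bound for the recording length (occurrence rates then
    need the true duration to be meaningful).
    """
    df = pd.read_csv(path)
    missing = set(CATALOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing catalog columns {sorted(missing)}")
    events = [
        SwrEvent(
            onset_s=float(r.onset_s),
            offset_s=float(r.offset_s),
            duration_ms=float(r.duration_ms),
            amplitude=float(r.amplitude),
            peak_time_s=float(r.peak_time_s),
            peak_envelope=float(r.peak_envelope),
            local_median=float(getattr(r, "local_median", 0.0)),
        )
        for r in df.itertuples()
    ]
    rec_id = str(df["recording_id"].iloc[0]) if len(df) else ""
    dur = recording_duration_s
    if dur is None:
        dur = max((e.offset_s for e in events), default=1.0)
        dur = max(dur, 1e-9)
    return EventCatalog(rec_id, events, dur)


def write_spectrogram(grid: SpectrogramGrid, path: str | Path) -> None:
    """Delimited matrix: header row of frequencies, first column of times."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s"] + [f"{f:g}" for f in grid.freqs_hz])
        for t, row in zip(grid.times_s, grid.power_db):
            w.writerow([f"{t:.6f}"] + [f"{p:.17g}" for p in row])


def read_spectrogram(path: str | Path) -> SpectrogramGrid:
    df = pd.read_csv(path)
    freqs = np.array([float(c) for c in df.columns[1:]])
    times = df.iloc[:, 0].to_numpy(dtype=float)
    power_db = df.iloc[:, 1:].to_numpy(dtype=float)
    return SpectrogramGrid(
        times_s=times, freqs_hz=freqs, power_db=power_db,
        power=10.0 ** (power_db / 10.0),
    )


def write_measurements(table: pd.DataFrame, path: str | Path) -> None:
    """Tidy measurement CSV: one row per recording/cell."""
    table.to_csv(path, index=False)


def read_measurements(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_manifest(metas: list[RecordingMeta], path: str | Path) -> None:
    """Study manifest: one row of RecordingMeta per recording."""
    pd.DataFrame([vars(m) for m in metas]).to_csv(path, index=False)


def read_manifest(path: str | Path) -> list[RecordingMeta]:
    df = pd.read_csv(path)
    return [
        RecordingMeta(
            recording_id=str(r.recording_id), genotype=str(r.genotype),
            treatment=str(r.treatment), region=str(r.region),
            duration_s=float(r.duration_s),
        )
        for r in df.itertuples()
    ]
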