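"""Event-aligned time-frequency power maps of ripple-filtered LFP.

Per-event spectrograms are built from a 100 ms segment of ripple-filtered
signal centered on the event's peak envelope, using a 15 ms sliding window
with 90% overlap.  A 15 ms window has a native DFT resolution of ~67 Hz,
far coarser than the requested 2 Hz grid, so power is evaluated by direct
discrete-time Fourier evaluation at each grid frequency (equivalent to
zero-padded DFT interpolation).  Maps are averaged across events in linear
power and converted to dB once at the end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import windows

from .ripples import EventCatalog, SwrEvent
from .trace import TimeSeriesTrace

__all__ = ["SpectrogramParams", "SpectrogramGrid", "event_spectrogram", "average_spectrogram"]

DB_FLOOR = -60.0


@dataclass(frozen=True)
class SpectrogramParams:
    """Spectrogram geometry: 100 ms segments, 15 ms Hann windows with 90%
    overlap (1.5 ms hop), frequency grid 100-300 Hz in 2 Hz steps."""

    segment_ms: float = 100.0
    window_ms: float = 15.0
    overlap_frac: float = 0.90
    f_lo: float = 100.0
    f_hi: float = 300.0
    f_step: float = 2.0
    taper: str = "hann"
    db_ref: str = "max"  # "max": normalize per map; "absolute": raw dB

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_frac < 1):
            raise ValueError("overlap_frac must lie in [0, 1)")
        if not self.f_lo < self.f_hi:
            raise ValueError("f_lo must be below f_hi")
        if self.f_step <= 0:
            raise ValueError("f_step must be positive")
        if not self.window_ms < self.segment_ms:
            raise ValueError("window must be shorter than the segment")

    @property
    def freqs_hz(self) -> np.ndarray:
        n = int(round((self.f_hi - self.f_lo) / self.f_step)) + 1
        return self.f_lo + self.f_step * np.arange(n)

    def n_windows(self, fs: float) -> int:
        seg = int(round(self.segment_ms / 1000.0 * fs))
        win = int(round(self.window_ms / 1000.0 * fs))
        hop = max(int(round(win * (1.0 - self.overlap_frac))), 1)
        return (seg - win) // hop + 1


@dataclass
class SpectrogramGrid:
    """Time x frequency power map aligned on an event peak.

    ``times_s`` are window-center offsets relative to the peak, symmetric
    about zero; ``freqs_hz`` the inclusive grid; ``power_db`` the dB map
    (floored at -60 dB); ``power`` the linear map it derives from.
    ``n_events`` records how many events were averaged.
    """

    times_s: np.ndarray
    freqs_hz: np.ndarray
    power_db: np.ndarray
    power: np.ndarray
    n_events: int = 1
    edge_padded: bool = False

    def __post_init__(self) -> None:
        if self.power_db.shape != (self.times_s.size, self.freqs_hz.size):
            raise ValueError("power matrix shape must be (n_times, n_freqs)")
        if not np.isfinite(self.power_db).all():
            raise ValueError("power map contains non-finite values")


def _to_db(power: np.ndarray, db_ref: str) -> np.ndarray:
    ref = power.max() if db_ref == "max" else 1.0
    if ref <= 0:
        return np.full_like(power, DB_FLOOR)
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(power / ref)
    return np.maximum(db, DB_FLOOR)


def _window_plan(params: SpectrogramParams, fs: float) -> tuple[int, int, int, np.ndarray]:
    """(segment, window, hop) in samples plus symmetric window-center offsets."""
    seg = int(round(params.segment_ms / 1000.0 * fs))
    win = int(round(params.window_ms / 1000.0 * fs))
    hop = max(int(round(win * (1.0 - params.overlap_frac))), 1)
    n_win = (seg - win) // hop + 1
    # center the window comb on the event peak so times are symmetric about 0
    span = (n_win - 1) * hop
    first_center = -span // 2 if span % 2 == 0 else -(span // 2)
    centers = first_center + hop * np.arange(n_win)
    return seg, win, hop, centers


def event_spectrogram(
    filtered_trace: TimeSeriesTrace,
    event: SwrEvent,
    params: SpectrogramParams = SpectrogramParams(),
) -> SpectrogramGrid:
    """Time-frequency power map of one event, aligned on its peak envelope.

    Extracts the ``segment_ms`` stretch of ripple-filtered signal centered
    on ``event.peak_time_s`` (zero-padded and flagged if the peak sits
    within half a segment of a trace edge), slides the tapered window
    across it and evaluates power at each grid frequency by direct DTFT.
    """
    fs = filtered_trace.fs
    if params.f_hi >= fs / 2:
        raise ValueError(f"f_hi={params.f_hi} must be below Nyquist ({fs / 2} Hz)")
    seg, win, hop, centers = _window_plan(params, fs)
    x = filtered_trace.samples
    peak = filtered_trace.index_at(event.peak_time_s)

    lo = peak - seg // 2
    hi = lo + seg
    edge = lo < 0 or hi > x.size
    segment = np.zeros(seg)
    s0, s1 = max(lo, 0), min(hi, x.size)
    segment[s0 - lo : s1 - lo] = x[s0:s1]

    if params.taper == "hann":
        w = windows.hann(win, sym=True)
    elif params.taper == "boxcar":
        w = np.ones(win)
    else:
        raise ValueError(f"unknown taper {params.taper!r}")

    freqs = params.freqs_hz
    n_idx = np.arange(win)
    # direct DTFT at grid frequencies: (n_freq, win) complex kernel
    kernel = np.exp(-2j * math.pi * np.outer(freqs, n_idx) / fs) * w
    wsum = w.sum()

    seg_center = seg // 2
    frames = np.empty((centers.size, win))
    for i, c in enumerate(centers):
        start = seg_center + c - win // 2
        frames[i] = segment[start : start + win]
    power = np.abs(frames @ kernel.T) ** 2 / (wsum**2)

    times = centers / fs
    return SpectrogramGrid(
        times_s=times,
        freqs_hz=freqs,
        power_db=_to_db(power, params.db_ref),
        power=power,
        n_events=1,
        edge_padded=edge,
    )


def average_spectrogram(
    filtered_trace: TimeSeriesTrace,
    catalog: EventCatalog,
    params: SpectrogramParams = SpectrogramParams(),
    include_edge: bool = False,
) -> SpectrogramGrid:
    """Element-wise mean of per-event power maps, aligned at event peaks.

    Averaging happens in linear power; the result is converted to dB once.
    Edge-padded events are excluded unless ``include_edge``.
    """
    maps = []
    edge_any = False
    for ev in catalog.events:
        g = event_spectrogram(filtered_trace, ev, params)
        if g.edge_padded and not include_edge:
            edge_any = True
            continue
        maps.append(g.power)
    if not maps:
        raise ValueError("no usable (non-edge) events to average")
    mean_power = np.mean(maps, axis=0)
    g0 = _window_plan(params, filtered_trace.fs)
    times = g0[3] / filtered_trace.fs
    return SpectrogramGrid(
        times_s=times,
        freqs_hz=params.freqs_hz,
        power_db=_to_db(mean_power, params.db_ref),
        power=mean_power,
        n_events=len(maps),
        edge_padded=edge_any,
    )
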