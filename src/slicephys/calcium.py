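"""Activity-related calcium transients from two-channel fluorescence.

The calcium statistic is dG/R = (G - G0) / R, where G is the green,
calcium-sensitive channel, G0 its baseline mean before stimulus onset, and
R the red, calcium-insensitive reference channel.  Dividing by R corrects
for dye loading and path-length differences between ROIs without assuming
a resting calcium level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace import TimeSeriesTrace

__all__ = ["FluorescencePair", "CaTransient", "delta_g_over_r", "transient_amplitude"]

COMPARTMENTS = ("soma", "dendrite")


@dataclass
class FluorescencePair:
    """Green/red traces for one ROI plus the stimulus timing.

    ``baseline_window_s`` is the (start, end) interval, in seconds, used to
    estimate G0; it must precede ``stimulus_onset_s`` and R must be
    strictly positive throughout.
    """

    G: TimeSeriesTrace
    R: TimeSeriesTrace
    stimulus_onset_s: float
    baseline_window_s: tuple[float, float]
    roi_id: str = ""
    compartment: str = "soma"

    def __post_init__(self) -> None:
        if len(self.G) != len(self.R) or self.G.fs != self.R.fs:
            raise ValueError("G and R must share length and sampling rate")
        b0, b1 = self.baseline_window_s
        if not b0 < b1 <= self.stimulus_onset_s:
            raise ValueError("baseline window must precede the stimulus onset")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"compartment must be one of {COMPARTMENTS}")
        if np.any(self.R.samples <= 0):
            raise ValueError("reference channel R must be strictly positive")


@dataclass
class CaTransient:
    """A quantified transient: the dG/R trace, its post-onset peak and the
    time from stimulus onset to that peak."""

    dgr_trace: TimeSeriesTrace
    amplitude: float
    time_to_peak_s: float


def delta_g_over_r(
    pair: FluorescencePair, baseline_stat: str = "mean", r_mode: str = "pointwise"
) -> TimeSeriesTrace:
    """Compute the dG/R trace: (G[i] - G0) / R[i].

    G0 is the mean of G over the baseline window ("median" available for
    heavy-tailed baselines).  R divides pointwise by default, the literal
    reading of the formula; ``r_mode="mean"`` divides by the baseline mean
    of R instead, useful for low-SNR reference channels.
    """
    g = pair.G.samples
    r = pair.R.samples
    b0, b1 = pair.baseline_window_s
    i0 = pair.G.index_at(b0)
    i1 = pair.G.index_at(b1)  # half-open [b0, b1): the sample at b1 (often
    base = g[i0:i1]           # the stimulus onset) is not part of the baseline
    if base.size < 3:
        raise ValueError(f"baseline window holds {base.size} samples; need >= 3")
    if baseline_stat == "mean":
        g0 = float(np.mean(base))
    elif baseline_stat == "median":
        g0 = float(np.median(base))
    else:
        raise ValueError(f"unknown baseline_stat {baseline_stat!r}")
    denom = r if r_mode == "pointwise" else float(np.mean(r[i0:i1]))
    dgr = (g - g0) / denom
    return TimeSeriesTrace(dgr, pair.G.fs, t0=pair.G.t0, units="dG/R", channel_id=pair.roi_id)


def transient_amplitude(
    dgr_trace: TimeSeriesTrace,
    stimulus_onset_s: float,
    response_window_s: float = 1.32,
) -> CaTransient:
    """Peak dG/R in [onset, onset + response window].

    The default window (1.32 s) covers a 320 ms current step plus a 1 s
    decay tail.  The raw (unsmoothed) post-onset maximum is reported.
    """
    i0 = int(round((stimulus_onset_s - dgr_trace.t0) * dgr_trace.fs))
    if not 0 <= i0 < len(dgr_trace):
        raise ValueError("response window lies outside the trace")
    i1 = int(round((stimulus_onset_s + response_window_s - dgr_trace.t0) * dgr_trace.fs)) + 1
    window = dgr_trace.samples[i0 : min(i1, len(dgr_trace))]
    if window.size == 0:
        raise ValueError("response window contains no samples")
    k = int(np.argmax(window))
    return CaTransient(
        dgr_trace=dgr_trace,
        amplitude=float(window[k]),
        time_to_peak_s=(i0 + k) / dgr_trace.fs + dgr_trace.t0 - stimulus_onset_s,
    )
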