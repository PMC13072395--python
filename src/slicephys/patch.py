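"""Patch-clamp analyses.

Current clamp: spike detection on voltage sweeps, firing frequency per
current step (F-I curve; the standard step series runs from -230 pA to
400 pA in 30 pA increments for 320 ms, so 220 pA is the 16th step), firing
pattern classification, and recording-stability QC (exclusion when access
resistance varies by more than 25% of its initial value or the resting
membrane potential drifts by more than 5 mV).

Voltage clamp: A-type K+ current isolation by digital subtraction of the
prepulse-inactivated protocol from the total-current protocol, and peak
current density (pA/pF) at a given step voltage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .trace import CellRecord, Sweep, SweepSet, TimeSeriesTrace

__all__ = [
    "FICurve",
    "QcResult",
    "detect_spikes",
    "firing_frequency",
    "build_fi_curve",
    "qc_exclude",
    "classify_firing",
    "isolate_a_type",
    "current_density",
    "STEP_SERIES_PA",
]

# the standard current-step series: -230 to 400 pA in 30 pA increments (22 steps)
STEP_SERIES_PA: tuple[float, ...] = tuple(float(c) for c in range(-230, 401, 30))


@dataclass
class FICurve:
    """Firing rate (Hz) as a function of injected current (pA).

    ``missing`` lists commanded steps for which no sweep was available;
    rates at those currents are NaN.
    """

    currents_pA: np.ndarray
    rates_hz: np.ndarray
    missing: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.currents_pA = np.asarray(self.currents_pA, dtype=float)
        self.rates_hz = np.asarray(self.rates_hz, dtype=float)
        if np.any(np.diff(self.currents_pA) <= 0):
            raise ValueError("currents must be strictly increasing")
        if np.any(self.rates_hz[np.isfinite(self.rates_hz)] < 0):
            raise ValueError("rates must be non-negative")

    def rate_at(self, current_pA: float) -> float:
        idx = np.flatnonzero(np.isclose(self.currents_pA, current_pA))
        if idx.size == 0:
            raise KeyError(f"no step at {current_pA} pA")
        return float(self.rates_hz[idx[0]])


def detect_spikes(
    voltage_trace: TimeSeriesTrace,
    threshold_mV: float = 0.0,
    refractory_ms: float = 1.0,
) -> np.ndarray:
    """Times (s) of upward crossings of ``threshold_mV``, separated by at
    least ``refractory_ms``.

    0 mV is a robust criterion for overshooting somatic spikes; use a lower
    threshold (e.g. -20 mV) for broad spikes that do not overshoot.
    """
    v = voltage_trace.samples
    above = v >= threshold_mV
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if above[0]:
        crossings = np.concatenate(([0], crossings))
    if crossings.size == 0:
        return np.array([])
    refr = refractory_ms / 1000.0 * voltage_trace.fs
    kept = [int(crossings[0])]
    for c in crossings[1:]:
        if c - kept[-1] >= refr:
            kept.append(int(c))
    return voltage_trace.t0 + np.array(kept) / voltage_trace.fs


def firing_frequency(sweep: Sweep, spike_times: np.ndarray) -> float:
    """Spikes during the command step divided by the step duration (Hz).

    Spikes outside the step interval are excluded with a warning.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    t0 = sweep.step_onset_s
    t1 = sweep.step_onset_s + sweep.step_dur_s
    inside = (spike_times >= t0) & (spike_times < t1)
    if inside.size and not inside.all():
        warnings.warn(
            f"{int((~inside).sum())} spike(s) outside the step interval excluded",
            stacklevel=2,
        )
    return float(inside.sum()) / sweep.step_dur_s


def build_fi_curve(
    cell: CellRecord,
    threshold_mV: float = 0.0,
    refractory_ms: float = 1.0,
    step_series: tuple[float, ...] = STEP_SERIES_PA,
) -> FICurve:
    """One firing rate per commanded current step.

    Missing steps leave NaN gaps and are flagged in ``missing``.
    """
    rates = np.full(len(step_series), np.nan)
    missing = []
    for i, c in enumerate(step_series):
        try:
            sweep = cell.sweeps.get(c)
        except KeyError:
            missing.append(c)
            continue
        spikes = detect_spikes(sweep.trace, threshold_mV, refractory_ms)
        rates[i] = firing_frequency(sweep, spikes)
    if missing:
        warnings.warn(f"missing sweeps for steps {missing}", stacklevel=2)
    return FICurve(np.array(step_series), rates, missing=tuple(missing))


@dataclass(frozen=True)
class QcResult:
    keep: bool
    reason: str = ""  # "access_resistance" | "rmp" | ""
    ra_max_frac_dev: float = 0.0
    rmp_max_abs_dev_mV: float = 0.0


def qc_exclude(
    cell: CellRecord,
    ra_max_frac: float = 0.25,
    rmp_max_mV: float = 5.0,
) -> QcResult:
    """Recording-stability QC.

    Excludes the cell if the access resistance deviates from its initial
    value by more than 25% (relative) or the resting membrane potential
    drifts by more than 5 mV (absolute) at any point.  The decision is a
    pure function of the series' extrema, so it is order-independent.
    """
    ra = np.asarray(cell.access_resistance_series, dtype=float)
    rmp = np.asarray(cell.rmp_series, dtype=float)
    ra_dev = float(np.max(np.abs(ra - ra[0])) / ra[0]) if ra[0] != 0 else np.inf
    rmp_dev = float(np.max(np.abs(rmp - rmp[0])))
    if ra_dev > ra_max_frac:
        return QcResult(False, "access_resistance", ra_dev, rmp_dev)
    if rmp_dev > rmp_max_mV:
        return QcResult(False, "rmp", ra_dev, rmp_dev)
    return QcResult(True, "", ra_dev, rmp_dev)


def classify_firing(
    spike_times: np.ndarray,
    burst_isi_ms: float = 10.0,
) -> str:
    """Classify the firing pattern at a just-suprathreshold step.

    Convention: "burst" when the first two inter-spike intervals are both
    below ``burst_isi_ms`` (>= 3 short-latency spikes); "doublet" when only
    the first ISI is that short; otherwise "regular".  No spikes at all
    yields "unclassified".  The thresholds are package conventions and are
    configurable.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size == 0:
        return "unclassified"
    isis_ms = np.diff(spike_times) * 1000.0
    if isis_ms.size >= 2 and isis_ms[0] < burst_isi_ms and isis_ms[1] < burst_isi_ms:
        return "burst"
    if isis_ms.size >= 1 and isis_ms[0] < burst_isi_ms:
        return "doublet"
    return "regular"


def isolate_a_type(protocol1: SweepSet, protocol2: SweepSet) -> SweepSet:
    """A-type K+ current by digital subtraction (protocol 1 - protocol 2).

    Both protocols must share step voltages, sampling rate and step-onset
    alignment; the subtraction is pointwise per step, aligned at the
    depolarization onset.
    """
    if len(protocol1) != len(protocol2):
        raise ValueError("protocols have different numbers of sweeps")
    out = []
    for s1, s2 in zip(protocol1, protocol2):
        if not np.isclose(s1.command, s2.command):
            raise ValueError(f"step mismatch: {s1.command} vs {s2.command} mV")
        if s1.trace.fs != s2.trace.fs:
            raise ValueError("sampling-rate mismatch between protocols")
        if not np.isclose(s1.step_onset_s, s2.step_onset_s):
            raise ValueError("step onsets are not aligned")
        n = min(len(s1.trace), len(s2.trace))
        diff = s1.trace.samples[:n] - s2.trace.samples[:n]
        tr = TimeSeriesTrace(
            diff, s1.trace.fs, t0=s1.trace.t0, units=s1.trace.units,
            channel_id=f"atype_{s1.command:+.0f}mV",
        )
        out.append(Sweep(tr, s1.command, s1.step_onset_s, min(s1.step_dur_s, s2.step_dur_s)))
    return SweepSet(out)


def current_density(a_type_sweep: Sweep, capacitance_pF: float) -> float:
    """Peak A-type current during the step, normalized to capacitance
    (pA/pF).  Peak = maximum over the step window (outward current)."""
    if not capacitance_pF > 0:
        raise ValueError("capacitance must be positive")
    window = a_type_sweep.trace.samples[a_type_sweep.step_slice]
    return float(window.max()) / capacitance_pF
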