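"""Core time-series containers.

Every stage of the pipeline consumes and produces :class:`TimeSeriesTrace`
objects.  Canonical internal units are seconds, Hz, mV, pA and pF; any unit
conversion happens at the I/O boundary, never inside an analysis stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

GENOTYPES = ("WT", "3xTG")
TREATMENTS = ("control", "UCP4")
REGIONS = ("CA1", "subiculum")


@dataclass
class TimeSeriesTrace:
    """A uniformly sampled signal.

    Parameters
    ----------
    samples
        Signal values (mV for voltage, pA for current, arbitrary units for
        fluorescence).
    fs
        Sampling rate in Hz, strictly positive.
    t0
        Time of the first sample in seconds.
    units
        Free-text unit label ("mV", "pA", "au").
    channel_id
        Free-text channel label.

    The time of sample ``i`` is ``t0 + i / fs``.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    units: str = ""
    channel_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("trace must be a 1-D array with at least one sample")
        if not np.isfinite(self.samples).all():
            raise ValueError("trace contains non-finite samples")
        if not (self.fs > 0 and np.isfinite(self.fs)):
            raise ValueError(f"sampling rate must be positive and finite, got {self.fs}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        """Length of the trace in seconds (n / fs)."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    def index_at(self, t_s: float) -> int:
        """Nearest sample index for a time in seconds (clipped to bounds)."""
        i = int(round((t_s - self.t0) * self.fs))
        return min(max(i, 0), self.samples.size - 1)

    def with_samples(self, samples: np.ndarray) -> "TimeSeriesTrace":
        """Copy of this trace with new sample values (same clock)."""
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class RecordingMeta:
    """Per-recording metadata: experimental group membership and length."""

    recording_id: str
    genotype: str
    treatment: str
    region: str
    duration_s: float

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}, got {self.genotype!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}, got {self.treatment!r}")
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}, got {self.region!r}")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")


@dataclass
class Sweep:
    """One patch-clamp sweep: a trace plus its command step.

    ``command`` is the step value in pA (current clamp) or mV (voltage
    clamp); the step occupies ``[step_onset_s, step_onset_s + step_dur_s)``.
    """

    trace: TimeSeriesTrace
    command: float
    step_onset_s: float
    step_dur_s: float

    def __post_init__(self) -> None:
        if not self.step_dur_s > 0:
            raise ValueError("step_dur_s must be positive")
        t_end = self.trace.t0 + self.trace.duration_s
        if self.step_onset_s < self.trace.t0 - 1e-12 or self.step_onset_s + self.step_dur_s > t_end + 1e-9:
            raise ValueError("step interval must lie within the sweep trace")

    @property
    def step_slice(self) -> slice:
        """Sample slice covering the command step."""
        i0 = self.trace.index_at(self.step_onset_s)
        i1 = int(round((self.step_onset_s + self.step_dur_s - self.trace.t0) * self.trace.fs))
        return slice(i0, min(i1, len(self.trace)))


@dataclass
class SweepSet:
    """Sweeps keyed by command step value."""

    sweeps: list[Sweep] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sweeps = sorted(self.sweeps, key=lambda s: s.command)

    def __len__(self) -> int:
        return len(self.sweeps)

    def __iter__(self):
        return iter(self.sweeps)

    @property
    def commands(self) -> np.ndarray:
        return np.array([s.command for s in self.sweeps])

    def get(self, command: float, atol: float = 1e-6) -> Sweep:
        for s in self.sweeps:
            if abs(s.command - command) <= atol:
                return s
        raise KeyError(f"no sweep with command {command}")


@dataclass
class CellRecord:
    """A patched cell: sweeps plus the monitoring series used for QC.

    ``access_resistance_series`` (MOhm) and ``rmp_series`` (mV) are the
    values logged over the course of the recording; QC works on their
    extrema relative to the initial value, so their spacing in time is
    irrelevant.
    """

    cell_id: str
    capacitance_pF: float
    access_resistance_series: Sequence[float]
    rmp_series: Sequence[float]
    sweeps: SweepSet = field(default_factory=SweepSet)
    firing_class: str = "unclassified"

    def __post_init__(self) -> None:
        if not self.capacitance_pF > 0:
            raise ValueError("capacitance must be positive")
        if len(self.access_resistance_series) == 0 or len(self.rmp_series) == 0:
            raise ValueError("monitoring series must be non-empty")
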