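"""Ground-truth-labeled synthetic inputs for every pipeline stage.

The generators stand in for animal recordings: each one produces a signal
with the statistical structure the corresponding analysis stage assumes,
together with the true quantities (event times, spike times, peak
currents, transient amplitudes) that the stage is supposed to recover.
All generators are pure functions of their parameters and seed.

The LFP simulator builds 1/f-like background noise by spectral shaping of
white Gaussian noise, then adds transient ripple packets (Gaussian-envelope
sinusoids in the 100-300 Hz band) riding on slow negative sharp-wave
deflections, with Poisson event timing thinned by a refractory gap.  The
signal-to-noise ratio of a packet is defined against the background's
ripple-band envelope SD — the same statistic the detector thresholds on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ripples import RippleDetectParams, bandpass_ripple, compute_envelope
from .trace import RecordingMeta, Sweep, SweepSet, TimeSeriesTrace

__all__ = [
    "RippleSimParams",
    "GroundTruth",
    "StudySimParams",
    "LifParams",
    "KCurrentParams",
    "CaSimParams",
    "simulate_lfp",
    "simulate_current_clamp",
    "simulate_k_current_protocols",
    "simulate_fluorescence_pair",
    "simulate_study",
    "lif_isi_s",
]

# envelope of a packet is Gaussian; its "true duration" is the interval
# where the envelope exceeds 10% of its peak: dur = 2*sigma*sqrt(2*ln 10)
_DUR_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(10.0)))


@dataclass(frozen=True)
class RippleSimParams:
    """Parameters of the synthetic LFP.

    ``snr`` scales the peak ripple envelope in multiples of the ripple-band
    envelope SD of the background noise.  ``sharp_wave_amp`` (mV) is the
    depth of the negative half-sine deflection under each packet, whose
    width follows the packet duration clipped to 40-100 ms.
    ``noise_rms_mv`` sets the broadband background RMS; slice LFPs are tens
    of microvolts, so 0.05 mV is used as a realistic scale.
    """

    fs: float = 10_000.0
    duration_s: float = 300.0
    event_rate_hz: float = 0.2
    ripple_freq_hz: tuple[float, float] = (150.0, 250.0)
    event_dur_ms: tuple[float, float] = (30.0, 80.0)
    snr: float = 6.0
    sharp_wave_amp: float = 0.15
    noise_exponent: float = 1.0
    noise_rms_mv: float = 0.05
    refractory_ms: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.event_rate_hz < 0:
            raise ValueError("event_rate_hz must be non-negative")
        lo, hi = self.ripple_freq_hz
        if not (0 < lo <= hi < self.fs / 2):
            raise ValueError("ripple_freq_hz must lie inside (0, fs/2)")
        dlo, dhi = self.event_dur_ms
        if not (0 < dlo <= dhi):
            raise ValueError("event_dur_ms bounds must be positive and ordered")
        if self.refractory_ms < 0:
            raise ValueError("refractory_ms must be non-negative")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")


@dataclass
class GroundTruth:
    """True event list emitted by a generator; the acceptance oracle.

    ``true_events`` holds ``(onset_s, offset_s, carrier_hz, peak_amp)``
    tuples, sorted and non-overlapping.  ``group_params`` retains the
    per-group generating parameters for study-level simulations.
    """

    true_events: list[tuple[float, float, float, float]] = field(default_factory=list)
    group_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ev = sorted(self.true_events, key=lambda e: e[0])
        for a, b in zip(ev, ev[1:]):
            if b[0] < a[1]:
                raise ValueError("ground-truth events overlap")
        self.true_events = ev

    def __len__(self) -> int:
        return len(self.true_events)


def _colored_noise(n: int, exponent: float, rms: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f**exponent, unit-free RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    out = np.fft.irfft(spec * scale, n=n)
    sd = out.std()
    if sd > 0:
        out *= rms / sd
    return out


def _band_envelope_sd(x: np.ndarray, fs: float) -> float:
    """Ripple-band (100-300 Hz) envelope SD of a signal — the background
    statistic the packet SNR and the detector threshold refer to.

    Estimated on at most the first 10 s: the envelope decorrelates within
    milliseconds, so a 10 s stretch pins the SD to well under 1%.
    """
    n = min(x.size, int(round(10.0 * fs)))
    tr = TimeSeriesTrace(x[:n], fs)
    env = compute_envelope(bandpass_ripple(tr, RippleDetectParams()))
    return float(np.std(env.samples))


def simulate_lfp(params: RippleSimParams) -> tuple[TimeSeriesTrace, GroundTruth]:
    """Synthesize an LFP trace with embedded ripple/sharp-wave events.

    Event centers follow a Poisson process of the requested rate, thinned
    so that consecutive centers are at least ``refractory_ms`` plus one
    maximal packet width apart (guaranteeing non-overlapping truth).  Each
    packet is a Gaussian-envelope sinusoid whose carrier is drawn uniformly
    from ``ripple_freq_hz`` and whose 10%-of-peak envelope width is drawn
    uniformly from ``event_dur_ms``; a synchronous negative half-sine
    sharp wave rides underneath.

    Returns the trace (mV) and the ground truth.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.fs))
    noise = _colored_noise(n, params.noise_exponent, params.noise_rms_mv, rng)
    sd_bg = _band_envelope_sd(noise, params.fs)

    max_width_s = max(params.event_dur_ms[1], 100.0) / 1000.0
    min_spacing = params.refractory_ms / 1000.0 + max_width_s
    if params.event_rate_hz > 0 and params.event_rate_hz * min_spacing >= 1.0:
        raise ValueError(
            "event rate too high for the refractory gap: expected occupancy "
            f"{params.event_rate_hz * min_spacing:.2f} >= 1"
        )

    # Poisson process of centers, thinned by the minimum spacing and kept
    # clear of the trace edges
    centers: list[float] = []
    if params.event_rate_hz > 0:
        t = 0.0
        margin = max_width_s / 2.0 + 0.01
        while True:
            t += rng.exponential(1.0 / params.event_rate_hz)
            if t >= params.duration_s - margin:
                break
            if t < margin:
                continue
            if centers and t - centers[-1] < min_spacing:
                continue
            centers.append(t)

    samples = noise
    truth_events = []
    tt = np.arange(n) / params.fs
    for c in centers:
        dur = rng.uniform(*params.event_dur_ms) / 1000.0
        carrier = rng.uniform(*params.ripple_freq_hz)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        sigma = dur * _DUR_TO_SIGMA
        peak_amp = params.snr * sd_bg
        i0 = max(int((c - dur / 2) * params.fs), 0)
        i1 = min(int(math.ceil((c + dur / 2) * params.fs)) + 1, n)
        t_loc = tt[i0:i1] - c
        envelope = peak_amp * np.exp(-(t_loc**2) / (2.0 * sigma**2))
        samples[i0:i1] += envelope * np.sin(2.0 * math.pi * carrier * t_loc + phase)
        # sharp wave: negative half-sine whose width tracks the packet
        sw_w = min(max(dur, 0.040), 0.100)
        j0 = max(int((c - sw_w / 2) * params.fs), 0)
        j1 = min(int(math.ceil((c + sw_w / 2) * params.fs)) + 1, n)
        t_sw = tt[j0:j1] - (c - sw_w / 2)
        samples[j0:j1] -= params.sharp_wave_amp * np.sin(math.pi * t_sw / sw_w)
        truth_events.append((c - dur / 2, c + dur / 2, carrier, peak_amp))

    trace = TimeSeriesTrace(samples, params.fs, units="mV", channel_id="lfp")
    return trace, GroundTruth(true_events=truth_events)


# ---------------------------------------------------------------------------
# current clamp: leaky integrate-and-fire sweeps


@dataclass(frozen=True)
class LifParams:
    """Leaky integrate-and-fire neuron used as current-clamp ground truth.

    Voltages in mV, times in ms, input resistance in MOhm (so pA x MOhm
    / 1000 = mV).  ``burst_current_pA`` > 0 enables a decaying transient
    drive at step onset producing 2-3 short-ISI spikes (burst mode).
    """

    v_rest: float = -65.0
    tau_ms: float = 20.0
    r_in_mohm: float = 100.0
    v_thresh: float = -45.0
    v_reset: float = -65.0
    refractory_ms: float = 2.0
    spike_peak_mv: float = 30.0
    spike_width_ms: float = 1.0
    noise_sd_mv: float = 0.0
    burst_current_pA: float = 0.0
    burst_tau_ms: float = 8.0
    fs: float = 10_000.0

    def __post_init__(self) -> None:
        if self.tau_ms <= 0:
            raise ValueError("membrane tau must be positive")
        if self.refractory_ms <= 0:
            raise ValueError("refractory must be positive")
        if self.v_thresh <= self.v_reset:
            raise ValueError("threshold must exceed reset")


def lif_isi_s(params: LifParams, step_pA: float) -> float:
    """Closed-form inter-spike interval for constant suprathreshold drive.

    ISI = refractory + tau * ln((R*I - (V_reset - E)) / (R*I - (V_th - E))),
    infinite below rheobase.
    """
    drive = step_pA * params.r_in_mohm / 1000.0  # mV
    top = drive - (params.v_reset - params.v_rest)
    bot = drive - (params.v_thresh - params.v_rest)
    if bot <= 0:
        return math.inf
    return params.refractory_ms / 1000.0 + params.tau_ms / 1000.0 * math.log(top / bot)


def simulate_current_clamp(
    step_pA: float,
    duration_ms: float = 320.0,
    neuron_params: LifParams = LifParams(),
    seed: int = 0,
    pre_ms: float = 50.0,
    post_ms: float = 50.0,
) -> tuple[Sweep, np.ndarray]:
    """One current-clamp sweep: LIF membrane response to a square step.

    The membrane is integrated with the exact exponential update; at each
    threshold crossing a stereotyped spike waveform (instant rise to
    ``spike_peak_mv`` at the crossing sample, 1 ms linear decay) is pasted
    into the voltage trace and the membrane resets after the absolute
    refractory period.  Returns the sweep and the true spike times (s).
    """
    p = neuron_params
    rng = np.random.default_rng(seed)
    fs = p.fs
    dt = 1.0 / fs
    n = int(round((pre_ms + duration_ms + post_ms) / 1000.0 * fs))
    onset = pre_ms / 1000.0
    i_on = int(round(onset * fs))
    i_off = int(round((pre_ms + duration_ms) / 1000.0 * fs))

    tau = p.tau_ms / 1000.0
    decay = math.exp(-dt / tau)
    refr = int(round(p.refractory_ms / 1000.0 * fs))
    v = p.v_rest
    volts = np.empty(n)
    spikes: list[int] = []
    hold_until = -1
    for i in range(n):
        drive = step_pA if i_on <= i < i_off else 0.0
        if p.burst_current_pA > 0 and i_on <= i < i_off:
            drive += p.burst_current_pA * math.exp(-(i - i_on) * dt / (p.burst_tau_ms / 1000.0))
        v_inf = p.v_rest + drive * p.r_in_mohm / 1000.0
        if i <= hold_until:
            v = p.v_reset
            volts[i] = v
            continue
        v = v_inf + (v - v_inf) * decay
        if p.noise_sd_mv > 0:
            v += p.noise_sd_mv * math.sqrt(dt / tau) * rng.standard_normal()
        if v >= p.v_thresh:
            spikes.append(i)
            hold_until = i + refr
            v = p.v_reset
            volts[i] = p.v_thresh
        else:
            volts[i] = v

    # paste spike templates: instant rise at the crossing sample, linear decay
    w = max(int(round(p.spike_width_ms / 1000.0 * fs)), 1)
    ramp = np.linspace(1.0, 0.0, w, endpoint=False)
    for s in spikes:
        seg = min(w, n - s)
        base = volts[s]
        volts[s : s + seg] = np.maximum(
            volts[s : s + seg], base + (p.spike_peak_mv - base) * ramp[:seg]
        )

    trace = TimeSeriesTrace(volts, fs, units="mV", channel_id=f"cc_{step_pA:+.0f}pA")
    sweep = Sweep(trace, command=step_pA, step_onset_s=onset, step_dur_s=duration_ms / 1000.0)
    return sweep, np.array(spikes) / fs


# ---------------------------------------------------------------------------
# voltage clamp: two-protocol A-type isolation


@dataclass(frozen=True)
class KCurrentParams:
    """Model K+ conductances for the two-protocol design.

    The transient (A-type) current activates as ``1 - exp(-t/tau_act)`` and
    inactivates as ``exp(-t/tau_inact)``; the sustained current activates
    slowly and does not inactivate.  A -20 mV / 200 ms prepulse (protocol
    2) fully inactivates the A-type component, so the protocol-1 minus
    protocol-2 subtraction isolates it.  Conductances in nS, so
    nS x mV driving force = pA.
    """

    g_a_ns: float = 50.0
    g_sus_ns: float = 30.0
    tau_act_ms: float = 2.0
    tau_inact_ms: float = 25.0
    tau_sus_ms: float = 50.0
    e_k_mv: float = -90.0
    capacitance_pF: float = 100.0
    noise_sd_pA: float = 0.0
    fs: float = 10_000.0
    step_mv: tuple[float, ...] = tuple(float(v) for v in range(-70, 30, 10))
    step_dur_s: float = 1.0
    pre_s: float = 0.05
    post_s: float = 0.05

    def __post_init__(self) -> None:
        if self.g_a_ns < 0 or self.g_sus_ns < 0:
            raise ValueError("conductances must be non-negative")


def _a_type_waveform(p: KCurrentParams, v_mv: float, t: np.ndarray) -> np.ndarray:
    drive = max(v_mv - p.e_k_mv, 0.0)
    act = 1.0 - np.exp(-t / (p.tau_act_ms / 1000.0))
    inact = np.exp(-t / (p.tau_inact_ms / 1000.0))
    return p.g_a_ns * drive * act * inact


def simulate_k_current_protocols(
    cell_params: KCurrentParams = KCurrentParams(), seed: int = 0
) -> tuple[SweepSet, SweepSet, dict[float, float]]:
    """Simulate the paired voltage-clamp protocols.

    Protocol 1 sweeps carry transient (A-type) plus sustained current;
    protocol 2 sweeps, acquired after the inactivating prepulse, carry the
    sustained component only.  Returns (protocol1, protocol2, true A-type
    peak amplitude in pA per step voltage).
    """
    p = cell_params
    rng = np.random.default_rng(seed)
    fs = p.fs
    n_pre = int(round(p.pre_s * fs))
    n_step = int(round(p.step_dur_s * fs))
    n_post = int(round(p.post_s * fs))
    n = n_pre + n_step + n_post
    t_step = np.arange(n_step) / fs

    sw1, sw2, truth = [], [], {}
    for v in p.step_mv:
        drive = max(v - p.e_k_mv, 0.0)
        sus = p.g_sus_ns * drive * (1.0 - np.exp(-t_step / (p.tau_sus_ms / 1000.0)))
        a = _a_type_waveform(p, v, t_step)
        truth[v] = float(a.max())
        for target, comp in ((sw1, sus + a), (sw2, sus)):
            x = np.zeros(n)
            x[n_pre : n_pre + n_step] = comp
            if p.noise_sd_pA > 0:
                x += p.noise_sd_pA * rng.standard_normal(n)
            tr = TimeSeriesTrace(x, fs, units="pA", channel_id=f"vc_{v:+.0f}mV")
            target.append(Sweep(tr, command=v, step_onset_s=p.pre_s, step_dur_s=p.step_dur_s))
    return SweepSet(sw1), SweepSet(sw2), truth


# ---------------------------------------------------------------------------
# two-channel fluorescence


@dataclass(frozen=True)
class CaSimParams:
    """Green/red fluorescence pair with an injected calcium transient.

    The transient rises instantly at ``stim_onset_s`` and decays
    exponentially with ``tau_decay_s``.  True peak dG/R = amp / r0 when
    noise-free.  Frame rate defaults to 3 Hz, typical of slow two-photon
    frame scanning.
    """

    g0: float = 1.0
    r0: float = 2.0
    amp: float = 1.0
    tau_decay_s: float = 0.5
    stim_onset_s: float = 2.0
    duration_s: float = 8.0
    fs: float = 3.0
    noise_sd: float = 0.0
    mult_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("reference level r0 must be positive")
        if self.tau_decay_s <= 0:
            raise ValueError("tau_decay_s must be positive")


def simulate_fluorescence_pair(
    ca_params: CaSimParams = CaSimParams(), seed: int = 0
) -> tuple[TimeSeriesTrace, TimeSeriesTrace, float]:
    """Simulate a (G, R) channel pair; returns (G, R, true peak dG/R)."""
    p = ca_params
    rng = np.random.default_rng(seed)
    n = int(round(p.duration_s * p.fs))
    t = np.arange(n) / p.fs
    kernel = np.where(t >= p.stim_onset_s, np.exp(-(t - p.stim_onset_s) / p.tau_decay_s), 0.0)
    g = p.g0 + p.amp * kernel
    r = np.full(n, p.r0)
    if p.mult_noise_sd > 0:
        g = g * (1.0 + p.mult_noise_sd * rng.standard_normal(n))
        r = r * (1.0 + p.mult_noise_sd * rng.standard_normal(n))
    if p.noise_sd > 0:
        g = g + p.noise_sd * rng.standard_normal(n)
        r = r + p.noise_sd * rng.standard_normal(n)
    gt = TimeSeriesTrace(g, p.fs, units="au", channel_id="G")
    rt = TimeSeriesTrace(r, p.fs, units="au", channel_id="R")
    return gt, rt, p.amp / p.r0


# ---------------------------------------------------------------------------
# study-level simulation (genotype x treatment design)


@dataclass(frozen=True)
class StudySimParams:
    """Per-group SWR statistics for a simulated 2x2 study.

    ``group_params`` maps (genotype, treatment) to (event_rate_hz,
    mean_event_dur_ms).  ``rate_fold_genotype`` is a convenience: building
    via :meth:`from_folds` multiplies the base rate for the disease
    genotype, emulating the increased occurrence seen in disease models.
    """

    group_params: dict[tuple[str, str], tuple[float, float]]
    n_recordings: int = 15
    duration_s: float = 60.0
    fs: float = 10_000.0
    snr: float = 20.0  # saturating: occurrence estimates are detector-limited, not SNR-limited
    region: str = "CA1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_recordings < 1:
            raise ValueError("n_recordings must be at least 1")
        for key, (rate, dur) in self.group_params.items():
            if rate <= 0 or dur <= 0:
                raise ValueError(f"non-positive rate/duration for group {key}")

    @classmethod
    def from_folds(
        cls,
        base_rate_hz: float = 0.2,
        base_dur_ms: float = 55.0,
        rate_fold_genotype: float = 1.0,
        rate_fold_treatment: float = 1.0,
        **kwargs,
    ) -> "StudySimParams":
        groups = {}
        for g in ("WT", "3xTG"):
            for tr in ("control", "UCP4"):
                rate = base_rate_hz
                if g == "3xTG":
                    rate *= rate_fold_genotype
                if tr == "UCP4":
                    rate *= rate_fold_treatment
                groups[(g, tr)] = (rate, base_dur_ms)
        return cls(group_params=groups, **kwargs)


def simulate_study(
    params: StudySimParams,
) -> list[tuple[TimeSeriesTrace, RecordingMeta, GroundTruth]]:
    """Simulate one recording set for a 2x2 (genotype x treatment) study.

    Each group contributes ``n_recordings`` independent LFP recordings
    drawn with the group's event rate and mean duration (durations uniform
    over mean +/- 40%).  Ground truth retains the generating parameters.
    """
    out = []
    ss = np.random.SeedSequence(params.seed)
    children = ss.spawn(4 * params.n_recordings)
    k = 0
    for (genotype, treatment), (rate, dur_ms) in sorted(params.group_params.items()):
        for r in range(params.n_recordings):
            seed = int(children[k].generate_state(1)[0] % (2**31))
            k += 1
            sim = RippleSimParams(
                fs=params.fs,
                duration_s=params.duration_s,
                event_rate_hz=rate,
                event_dur_ms=(0.6 * dur_ms, 1.4 * dur_ms),
                snr=params.snr,
                seed=seed,
            )
            trace, truth = simulate_lfp(sim)
            truth.group_params = {
                "genotype": genotype,
                "treatment": treatment,
                "event_rate_hz": rate,
                "mean_event_dur_ms": dur_ms,
            }
            meta = RecordingMeta(
                recording_id=f"{genotype}_{treatment}_{r:02d}",
                genotype=genotype,
                treatment=treatment,
                region=params.region,
                duration_s=params.duration_s,
            )
            out.append((trace, meta, truth))
    return out
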