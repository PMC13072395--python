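# Methods

This note documents the models, conventions and numerical choices behind
`slicephys`, in the spirit of the methods documentation of simulation and
statistics packages: what each stage computes, which parameters matter,
what the synthetic data do and do not emulate, and where genuinely open
design choices were resolved.

## Sharp-wave-ripple detection

The detector operates on a uniformly sampled LFP trace (canonically
10 kHz, mV) and applies, in order:

1. **Band-pass, 100–300 Hz, zero phase.** 4th-order Butterworth run
   forward and reverse. The filter is applied as cascaded second-order
   sections: the direct-form coefficients of a narrow-band order-4
   band-pass are ill-conditioned and leave interior forward/backward
   asymmetry of ~1e-7, while biquads keep it at machine precision
   (~1e-14). Edge handling is odd-reflection padding of 3·(2·order + 1)
   = 27 samples, fixed for reproducibility; the start-up transient decays
   with the largest pole radius (0.9875 per sample, i.e. below 1e-9
   within ~1650 samples), which is what "away from edges" means for the
   zero-phase contract. Two passes square the magnitude response, so a
   tone at a −3 dB band edge emerges at amplitude ½.
2. **Envelope.** Modulus of the analytic (Hilbert) signal. No smoothing.
3. **Threshold.** Candidates are maximal runs of envelope samples
   strictly above 3.5× the envelope SD computed over the entire analyzed
   segment, events included; the SD is computed once and never updated
   by later stages. The statistic is scale-free, so detections are
   invariant under any positive gain applied to the trace. A
   zero-variance envelope yields no candidates, with a warning.
4. **Duration bounds.** Candidates lasting less than 10 ms or more than
   200 ms are excluded; the bounds are inclusive (a run of exactly
   10.0 ms is kept), counting both boundary samples.
5. **Merge.** Consecutive events with a gap strictly below 15 ms are
   fused (onset of the first, offset of the second, the larger envelope
   peak), left to right until a fixpoint, so chains collapse into one
   event. Merged events that exceed the 200 ms cap are then removed
   rather than resurrected.
6. **Boundary refinement.** One median is computed over the
   concatenation of the 15 ms broadband segments before the onset and
   after the offset. The refined onset is the first broadband sample
   below that median within a search window around the envelope onset;
   the refined offset is the last such sample around the envelope
   offset. The window half-width is 10 ms by default — the width is a
   package convention (comparable to the 15 ms context segments) because
   no standard exists. If a window contains no sub-median sample the
   envelope boundary is kept and the event is flagged `fallback`; events
   whose context segments were clamped at the trace ends are flagged
   `edge`. When two events sit 15–20 ms apart both refined boundaries
   could cross; the search is clipped at the midpoint of the
   inter-candidate gap so catalogs stay disjoint.

Duration is the time between refined boundaries; amplitude is the
broadband minimum within them minus the local median (signed; a
magnitude accessor is provided). Occurrence is events per second of
recording; a catalog with zero events carries a `no_activity` flag and
is excluded from group occurrence statistics, with the exclusion logged
under a machine-readable reason code.

### Operating characteristics of the threshold

"3.5× the SD of the envelope" places the threshold about 2.3× the
band-limited signal SD, because the envelope of Gaussian band noise is
Rayleigh (SD ≈ 0.655 of the band SD). The noise tail above that level is
substantial (P ≈ 0.07 per sample), so on a pure-noise trace the detector
reports a small but nonzero false-event rate (~0.1 Hz of ≥10 ms runs at
these settings) — consistent with the practice of confirming detections
by eye. In recordings with clear ripples the events themselves inflate
the whole-segment envelope SD that the threshold is anchored to, pushing
it into the far noise tail; in that saturating regime (packet envelopes
~20× the background envelope SD in the simulations used here) measured
sensitivity and precision against ground truth are ≥ 0.98 and the
median absolute duration error is below 10 ms. Validation therefore
quotes detector recovery in the saturating regime and treats the
permissive-threshold false-event rate as a property of the method, not a
bug.

## Event-aligned spectrograms

100 ms segments of ripple-filtered signal centered on each event's peak
envelope; 15 ms Hann windows (symmetric taper) with 90% overlap (1.5 ms
hop), 57 windows whose centers are symmetric about the event peak. A
15 ms window has a native DFT resolution of ~67 Hz, far coarser than the
requested 2 Hz grid, so power is evaluated by direct discrete-time
Fourier evaluation at each of the 101 grid frequencies (equivalent to
zero-padded interpolation); power is normalized by the squared window
sum. Maps are averaged across events in linear power and converted to
dB once (averaging dB values would change the estimator), normalized to
the map maximum with a −60 dB floor; an absolute-dB mode is available.
Events whose segment would cross a trace edge are zero-padded and
flagged, and excluded from averages by default.

Note the physical resolution limit: a pure in-grid tone's power spreads
over the ~±133 Hz Hann main lobe, not a handful of 2 Hz bins; the sharp
statements are that the per-slice argmax sits on the carrier bin and
that ≥90% of in-grid mass lies within the main-lobe half-width.

## Patch-clamp analyses

Spikes are upward crossings of 0 mV separated by at least 1 ms
(configurable; −20 mV suits non-overshooting spikes). Firing frequency
is spikes during the step divided by the step duration, counted over the
full 320 ms step. The F–I curve covers the 22-step series −230 … 400 pA;
220 pA is the 16th step. QC excludes a cell when the access resistance
deviates from its initial value by more than 25% (relative) or the
resting potential drifts more than 5 mV at any time; both rules are pure
functions of the series extrema and the triggering rule is reported.
Firing-pattern labels (burst / doublet / regular) use a leading-ISI
convention — burst: first two ISIs < 10 ms; doublet: only the first —
standing in for lab-specific criteria that are not standardized;
thresholds are configurable and the convention is deliberately simple.

A-type K⁺ current isolation is the pointwise difference of the
total-current protocol and the prepulse-inactivated protocol, aligned at
the depolarization onset, requiring matching step voltages and sampling
rates. Current density is the peak outward current during the step
divided by capacitance. No liquid-junction-potential correction is
applied anywhere.

## ΔG/R calcium transients

ΔG/R = (G − G₀)/R. G₀ is the mean of G over the baseline window
(median available); the window is half-open, so the sample at the
stimulus onset is not part of the baseline. R divides pointwise (the
literal formula); a baseline-mean-R mode exists for weak reference
channels. The transient amplitude is the raw maximum of ΔG/R within
the response window (default 1.32 s: a 320 ms step plus a 1 s decay
tail). Invariances: adding a constant to G cancels through G₀; scaling
(G − G₀) and R together cancels; scaling R alone divides.

## Synthetic data

All generators are pure functions of (parameters, seed).

**LFP.** Background is white Gaussian noise spectrally shaped to
1/f^α (α = 1 by default), scaled to 0.05 mV RMS — a realistic magnitude
for slice LFPs, chosen as a convention since field recordings vary
widely. Events are Gaussian-envelope sinusoids with carriers drawn
uniformly in 150–250 Hz and "true duration" defined as the interval
where the envelope exceeds 10% of its peak (making ground-truth duration
unambiguous); packet timing is a Poisson process thinned so consecutive
centers are at least one refractory period plus one maximal packet width
apart, which guarantees non-overlapping truth. Packet peak envelope is
`snr` × the background's ripple-band envelope SD — the same statistic
the detector thresholds on — with the SD measured on the first 10 s of
the noise-only signal. A negative half-sine sharp wave rides under each
packet; its width follows the packet duration clipped to 40–100 ms, so
boundary refinement sees a deflection commensurate with the event. The
simulator does not emulate non-stationary baselines, epileptiform
discharges, movement artifacts or electrode drift, so passing tests
bound algorithmic correctness, not robustness to such real-data
features.

**Current clamp.** Leaky integrate-and-fire neuron (rest −65 mV, τ =
20 ms, Rin = 100 MΩ, threshold −45 mV, 2 ms refractory) integrated with
the exact exponential update; an optional decaying onset current
produces burst-like leading ISIs. Spike waveforms are pasted templates
with an instant rise at the crossing sample and a 1 ms linear decay, so
threshold-crossing detection recovers the true spike sample exactly; the
closed-form constant-drive ISI provides an independent oracle.

**Voltage clamp.** Transient conductance activating as 1 − e^(−t/τa)
(τa = 2 ms) and inactivating as e^(−t/τi) (τi = 25 ms), plus a slowly
activating non-inactivating sustained conductance; protocol 2 carries
the sustained component only, emulating full inactivation by the
prepulse. Driving force is (V − EK), EK = −90 mV.

**Fluorescence.** G = G₀ + amp·(instant rise, exponential decay τ =
0.5 s) and constant R, each with optional additive/multiplicative
Gaussian noise, at a 3 Hz frame rate typical of slow frame scanning.
True peak ΔG/R = amp/R₀.

**Study level.** One LFP per recording with group-specific rates and
durations over the 2×2 design, seeds spawned per recording from a root
seed; ground truth retains the generating group parameters.

## Statistics

**ROUT (one-sample form).** The regression procedure degenerates for a
single group to a robust location/scale fit: location = median, scale =
the 68.27th percentile of absolute residuals with an n/(n−1)
small-sample correction (RSDR). Each point's |residual|/RSDR is referred
to a t distribution on n−1 df and the p-values are screened by
Benjamini–Hochberg at FDR Q, default 1% (the customary setting; applied
per group, not on the pooled table). Under clean normal samples the
point-wise flag rate stays below ~Q.

**Rank tests.** Mann–Whitney: exact null enumeration when both samples
have ≤8 observations and no ties, otherwise the normal approximation
with tie correction; always two-tailed. Wilcoxon signed-rank: zero
differences dropped, exact for ≤15 non-zero pairs without tied
magnitudes. Both are cross-checked in the tests against full enumeration
oracles.

**2×2 ANOVA + Fisher's LSD.** Type III sums of squares with sum-to-zero
contrasts (identical to the classical decomposition when balanced;
appropriate for the unequal n typical of slice studies). Sums of squares
below machine precision relative to the total variation are snapped to
zero so exact-arithmetic inputs yield F = 0 / p = 1 rather than rounding
residue. LSD compares all cell pairs with the pooled residual MS on the
residual df, two-sided and uncorrected, and is reported regardless of
the omnibus outcome (with the omnibus attached) — it does not control
the family-wise error rate. Cells with fewer than 2 units trigger an
insufficient-replication warning. Units of analysis are
recordings/cells, not animals.

**Operating characteristics.** `power_check` replicates full simulated
studies through detection and ANOVA and reports rejection rates per
effect. The shipped validation runs 200 null replicates (10
recordings/group, 48 s at 2 kHz sampling — the band sits well below the
1 kHz Nyquist, and shorter, lower-rate recordings keep the check fast)
and 50 effect replicates (2-fold genotype occurrence effect, 15
recordings/group). With 200 replicates the 95% binomial interval around
α = 0.05 is ±0.030 (it would be ±0.019 at 500); measured null genotype
rejection is ~0.05 and power against the 2-fold effect ~1.0. These
problem sizes are the package's validation defaults; all replicate
counts are parameters.

## Known limitations

- The detector's false-event rate under pure noise is nonzero by
  construction of the permissive envelope threshold (see above);
  applications near threshold should confirm events independently.
- Firing-pattern classification thresholds are conventions, not
  validated criteria.
- No ROI extraction from image stacks: the calcium module consumes
  per-ROI traces.
- ABF reading requires the optional `pyabf` dependency; without it the
  CSV dialect is the only input path.
- Statistics assume independent units; no mixed-effects modeling of
  animal-level clustering is provided.
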