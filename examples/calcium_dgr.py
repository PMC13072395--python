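"""Quantify a calcium transient as dG/R from a two-channel recording.

Simulates green (calcium-sensitive) and red (reference) fluorescence
traces with a known injected transient, computes dG/R = (G - G0)/R and
reports the post-stimulus peak.
"""

from slicephys import (
    CaSimParams,
    FluorescencePair,
    delta_g_over_r,
    simulate_fluorescence_pair,
    transient_amplitude,
)

params = CaSimParams(amp=1.0, r0=2.0, noise_sd=0.03, stim_onset_s=2.0)
g, r, truth = simulate_fluorescence_pair(params, seed=4)
pair = FluorescencePair(g, r, stimulus_onset_s=2.0, baseline_window_s=(0.0, 2.0),
                        roi_id="soma01", compartment="soma")
dgr = delta_g_over_r(pair)
res = transient_amplitude(dgr, stimulus_onset_s=2.0)

print(f"true peak dG/R:      {truth:.3f}")
print(f"recovered peak dG/R: {res.amplitude:.3f} at +{res.time_to_peak_s:.2f} s")
# dG/R divides the baseline-subtracted green signal by the calcium-
# insensitive red channel, so the peak is dye- and path-length-corrected;
# at 3% channel noise the recovered peak sits within a few percent of truth.
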