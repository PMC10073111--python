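"""Signal-quality gating and joint ECG/PPG window selection.

A clean coupled waveform pair passes both gates; injected artifacts (a
5 mV spike, a 20-s PPG flat-line) trip the amplitude and stationarity
gates, pushing the selected joint 60-s window to the second minute.
"""

from edecomp.quality import (
    assess_ecg_quality,
    assess_ppg_quality,
    preprocess_and_select_window,
)
from edecomp.synth import ArtifactSpec, generate_rr_series, synthesize_waveform_pair

rr = generate_rr_series(mean_hr=72, lf_amplitude=25, hf_amplitude=15,
                        noise_sd=8, duration=180, seed=0)

clean_ecg, clean_ppg = synthesize_waveform_pair(rr, pat=0.25,
                                                perfusion_index=2.0, seed=0)
art = ArtifactSpec(spikes=[(10.0, 5.0)], flatlines=[(20.0, 20.0, "ppg")])
bad_ecg, bad_ppg = synthesize_waveform_pair(rr, pat=0.25, perfusion_index=2.0,
                                            artifact_spec=art, seed=0)

for name, rep in [
    ("clean ECG ", assess_ecg_quality(clean_ecg.slice(0, 60))),
    ("spiked ECG", assess_ecg_quality(bad_ecg.slice(0, 60))),
]:
    hr = f"{rep.detected_hr:.1f} bpm" if rep.detected_hr else "none"
    print(f"{name}: passed={rep.passed} reasons={rep.reasons} HR={hr}")
for name, rep in [
    ("clean PPG ", assess_ppg_quality(clean_ppg.slice(0, 60))),
    ("flat PPG  ", assess_ppg_quality(bad_ppg.slice(0, 60))),
]:
    print(f"{name}: passed={rep.passed} reasons={rep.reasons}")

sel = preprocess_and_select_window(bad_ecg, bad_ppg, assessment_minutes=3)
print(f"\nartifacts confined to [0, 60) s -> selected window starts at "
      f"{sel.start_s:.0f} s; filtered ECG now at {sel.ecg.fs:.0f} Hz "
      f"({len(sel.ecg.samples)} samples)")
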