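"""Heart-rate variability and pulse arrival time against ground truth.

The generator plants an SDRR (via LF/HF modulation and beat noise), a PAT
and a perfusion index; the measurement chain (QC window -> R-peak
detection -> HRV/PAT) recovers them from the rendered waveforms.
"""

from edecomp.pipeline import waveform_features_from_pair
from edecomp.synth import generate_rr_series, synthesize_waveform_pair

rr = generate_rr_series(mean_hr=70, lf_amplitude=30, hf_amplitude=20,
                        noise_sd=10, duration=90, seed=3)
ecg, ppg = synthesize_waveform_pair(rr, pat=0.25, perfusion_index=2.0, seed=4)
wf = waveform_features_from_pair(ecg, ppg)

print(f"planted: SDRR {rr.target_sdrr:.1f} ms, PAT 250.0 ms")
print(f"measured from waveforms:")
print(f"  SDRR      {wf['sdrr']:.1f} ms")
print(f"  RMSSD     {wf['rmssd']:.1f} ms")
print(f"  pRR50     {wf['prr50']:.1f} %")
print(f"  tri index {wf['tri_index']:.2f}")
print(f"  TINN      {wf['tinn']:.1f} ms")
print(f"  PAT       {1000 * wf['pat_mean']:.1f} ms over {wf['pat_n_pairs']} "
      "beat pairs")
print(f"  LF peak   {wf['lf_peak']:.3f} Hz, LF/HF ratio {wf['lf_hf_ratio']:.2f}")
print("\nPAT error is within one 125-Hz sample (8 ms) on clean signals; "
      "frequency-domain values here come from the filtered ECG signal's "
      "PSD (see docs/methods.md for the tachogram alternative).")
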