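# Methods

This note documents the models, numerical choices and limitations of the
`edecomp` pipeline: what is simulated, how each quantity is computed, and
what the passing test suite does and does not establish about real
monitored-ED data.

## Study design encoded by the pipeline

A visit enters the cohort only if it is *grossly stable*: HR ≤ 110 bpm,
SpO2 ≥ 90 %, MAP ≥ 65 mmHg at triage and at every 1-Hz sample of the first
15 minutes of monitoring (the assessment period), with at least one
measurement of each vital channel and each waveform. Models may use only
triage data and the assessment period. Outcomes are strict crossings of
one-minute channel means — HR > 110, SpO2 < 90, MAP < 65 — inside a window
of 60/90/120 minutes after assessment (90 is primary), plus the composite
outcome minute-level MEWS ≥ 4. Minute means rather than raw samples define
outcomes to suppress single-sample noise; a raw-sample mode exists in
`label_outcomes` consumers via `minute_means` but the single-minute-mean
crossing is the default, and no persistence beyond one minute is required.

Mean arterial pressure obeys MAP = SBP/3 + 2·DBP/3 throughout (checked at
construction to 0.1 mmHg).

## Synthetic cohort model

The generator is the package's study population; its defaults are the
conditions under which all distributional tests run.

* **Outcome prevalences** default to a stable adult ED cohort:
  tachycardia 6.11 %, hypoxia 11.20 %, hypotension 2.33 %. Events are
  Bernoulli draws driven by per-outcome risks `r_k = 0.7·z + √(1−0.49)·ε_k`
  with a shared standard-normal latent `z`; a visit decompensates on
  outcome *k* iff `r_k` exceeds the (1−p_k) normal quantile, so realized
  fractions are exactly binomial in n. Onset times are uniform integer
  minutes over the follow-up period (default 120 min).
* **Recoverable signal.** The latent tilts what a clinician would expect:
  assessment-period trend slopes (HR +0.25 bpm/min per SD of tachycardia
  risk; SpO2 −0.05 %/min; MAP −0.20 mmHg/min), SDRR
  `40·exp(−0.35·z)` ms and perfusion index `1.8·exp(−0.35·z)` %, each with
  log-normal visit-level noise. These effect sizes were chosen once to
  give a clearly learnable but not trivial signal (single-feature
  correlations with the latent around 0.5–0.7) and are configurable.
* **Vitals streams** are 1-Hz: baseline + slope·t + Gaussian noise
  (HR σ=1.5 bpm, RR 1.0, SpO2 0.5 %, MAP 2.0 mmHg) during assessment;
  afterwards the linear trend relaxes with a 10-minute e-folding so
  uneventful visits do not drift across thresholds. From an event's onset
  the outcome channel ramps over 60 s to a plateau beyond its threshold
  (e.g. HR ≈ 116 bpm) and is clipped to stay strictly beyond it for the
  rest of the record; plateau extremity is randomly exaggerated
  (half-normal, e.g. σ=9 bpm for HR) so that the composite MEWS ≥ 4
  outcome has a small emergent prevalence (~1–3 %). Baselines are capped
  so that baseline + slope·15 min + 4σ of noise respects the inclusion
  thresholds — risky visits therefore start slightly lower/higher, which
  is also physiologically sensible.
* **Charting.** SBP/DBP/temperature are emitted every 30 minutes (the
  charting interval of intermittent sphygmomanometry is institution
  specific; 30 min is a configurable guess), with SBP/DBP derived from the
  MAP trajectory under a constant pulse pressure.
* **Beat trains.** RR(t) = 60000/HR + LF·sin(2π·0.1t) + HF·sin(2π·0.25t)
  + N(0, σ²), clipped at a 200-ms floor; the implied SD is
  √(LF²/2 + HF²/2 + σ²). Per-visit LF:HF:σ are fixed at 1:0.7:0.5 of the
  target SDRR.
* **Waveforms.** ECG beats are a static sum-of-Gaussians template (P, Q,
  R ≈ 1 mV, S, T) at 500 Hz — unambiguous R-peaks, no pathology
  simulation. The PPG is an asymmetric (fast-rise/slow-fall) pulse at
  125 Hz whose apex lags the R-peak by exactly the configured PAT and
  whose AC/DC ratio equals perfusion_index/100; pulse widths scale with
  the mean RR interval so fast rates keep a positively skewed waveform
  instead of degenerating to a sinusoid. Artifacts (ECG spikes, flat-line
  holds, dropouts) are injectable at stated times.
* **Laziness and determinism.** Streams and waveforms are regenerated on
  access from stored parameters and per-visit child seeds, so cohorts of
  thousands of visits hold only tables in memory; identical configurations
  are byte-identical.

What the generator does **not** emulate: realistic disease trajectories,
arrhythmias, pediatric physiology, cross-channel artifact correlation,
respiratory-rate-coupled HF frequency drift, or measurement-device
quantization. Passing tests therefore demonstrate that the *pipeline*
recovers planted signal under controlled conditions — not that the planted
effect sizes match any real cohort.

## Signal quality

R-peak detection follows Hamilton's recipe: 8–20 Hz bandpass,
differentiation, rectification, 80-ms moving-average integration, then an
adaptive threshold placed 0.3125 of the way between running noise- and
signal-peak averages (EWMA weight 0.125) with a 200-ms refractory period;
accepted detections snap to the raw-signal extremum within ±60 ms. On
clean synthetic ECGs each beat is located within one raw sample (2 ms).

Gates: ECG fails on undetectable HR, HR outside 25–300 bpm, or any
|sample| > 4 mV. PPG fails on non-positive sample skewness, mean
beat-template correlation < 0.8, or > 5 % of the segment stationary
(running 2-s SD below 5 % of the segment SD). The numeric PPG thresholds
are package defaults (the literature reports such gates without universal
values); all are fields of `QCThresholds`.

Window selection scans non-overlapping 60-s windows from t = 0 — the
simplest reading of "first acceptable window"; an overlapping scan would
only move starts earlier. The selected ECG window is bandpassed 3–45 Hz
(3rd-order Butterworth, zero-phase) and decimated ×4 to 125 Hz; the 45-Hz
edge lies below the post-decimation Nyquist (62.5 Hz), so the bandpass is
also the anti-alias filter. The PPG window gets a 4th-order Butterworth
0.5–8 Hz bandpass (standard pulse-wave band; configurable).

## Engineered features

Time-domain HRV from RR intervals (ms): SDRR is the sample SD (n−1);
RMSSD the root-mean-square of successive differences; pRR50 the percentage
of successive differences **strictly** exceeding 50 ms; the triangular
index is N divided by the peak bin count of the RR histogram with the
conventional 1/128-s (7.8125-ms) bins aligned to multiples of the bin
width; TINN is by default the plain width of the occupied histogram
support (the literal "width of the RR histogram"), with the classical
least-squares triangular-interpolation variant available via
`tinn_method="interpolation"`. Fewer than 3 intervals yields missing
values rather than an error.

Frequency-domain HRV uses a Hann-windowed full-length Welch PSD. Bands:
LF [0.04, 0.15) Hz, HF [0.15, 0.4] Hz; per band the peak frequency,
absolute power (Riemann sum × Δf) and power relative to the 0.04–0.4 Hz
total; LF/HF is missing (not infinite) when HF power is zero. Two
substrates are supported and tested: the filtered 60-s **ECG signal
itself** (the deployment default in the measured-waveform path) and the
4-Hz cubic-resampled **RR tachogram** (the conventional HRV substrate and
the only option when no waveform was rendered). The two are *not*
interchangeable numerically — ECG-signal band powers are dominated by
waveform morphology — which is exactly why both modes exist and are kept
separate.

PAT: for each detected R-peak the candidate PPG peak is the first one
strictly after it; the pair is discarded when the delay exceeds the RR
interval beginning at that R-peak (the last peak reuses the final
interval); PAT is the mean of kept delays. PPG peaks are detected on the
filtered signal but refined to the raw local maximum within ±40 ms,
because zero-phase smoothing of an asymmetric pulse shifts its apex
(~10 ms here); with refinement the round-trip error is within one 125-Hz
sample (8 ms). The systolic **peak** (not the foot) defines PAT.

## Cohort tables

Minute trends: OLS slope of the one-minute means on the minute index
(units/min), missing minutes dropped, plus the first minute mean as the
level anchor; the intercept is not a separate feature. The first-vitals
block covers HR/RR/SpO2/MAP from the continuous channels plus the first
charted SBP/DBP.

MEWS components (neurologic omitted): SBP ≤70→3, 71–80→2, 81–100→1,
101–199→0, ≥200→2; HR <40→2, 40–50→1, 51–100→0, 101–110→1, 111–129→2,
≥130→3; RR <9→2, 9–14→0, 15–20→1, 21–29→2, ≥30→3; Temp <35→2,
35–38.4→0, ≥38.5→2. Bands are treated as continuous half-open intervals
at the published integer edges (a minute-mean HR of 50.5 scores with the
40–50 band). HR and RR use same-minute means; SBP and temperature use the
last carried-forward observation; minutes before any component's first
observation have a missing total. The table lives in a module-level dict
so variants are testable.

Splitting: visits are sorted by arrival; the latest 12.5 % form the
provisional test set and the arrival time of its first visit is the
cutoff. A patient with visits on both sides of the cutoff has **all**
visits moved to train — chronology and patient-disjointness cannot both be
satisfied for straddlers, and test-set purity wins. Earlier visits are
split into train/validation by seeded patient-grouped assignment
accumulating patients until the 12.5 % validation target is met.

Triage encoding (57 columns): age; gender as two indicator columns
(female, male — a two-level one-hot that also represents unknown as both
zero); ESI as an ordinal 1–5; triage temperature; six triage vitals (HR,
RR, SpO2, MAP, SBP, DBP); 46 one-hot chief-complaint indicators.
Temperature is included because attribution analyses need it even though
it is not part of the stability screen.

## Waveform encoder

A two-channel (ECG, PPG) 60-s 125-Hz input (2 × 7500) passes through four
1-D convolutions (kernel 15, stride 2, channels 16/32/64/64, ReLU),
sinusoidal positional encoding, two pre-norm transformer blocks (4 heads,
model dim 64, GELU feed-forward 128), token mean-pooling, a 32-unit ReLU
layer, an 8-unit embedding layer (4 dimensions per modality by
convention) and a single-logit head. It is implemented on a small
reverse-mode autograd engine over numpy (`edecomp.encoder.autograd`),
verified against numeric differentiation. Training: Adam, binary
cross-entropy on decompensation labels, triangular cyclic learning rate
between 1e-4 and 1e-2 with one cycle per 10 epochs, seeded shuffling;
default 5 epochs (desk scale; 60 is the full-scale setting). The encoder
trains from random initialization — no pre-trained rhythm-classification
weights are used — and embeddings for feature tables must be fit on
training-split visits only to avoid leakage. Layer counts and widths are
sized to train in minutes on one CPU and are all configurable.

## Risk models

LightGBM binary classifiers (`deterministic=true`), one per task × window
× feature set. Tuning is a seeded random search over num_leaves 15–255,
depth 3–12, learning rate 0.01–0.3 (log-uniform), min_child_samples
5–100, feature/bagging fraction 0.5–1.0, L1/L2 0–5, selecting by
validation AUROC; a transparent substitute for black-box auto-tuners.
The best configuration is then refit across `n_seeds` values of the
ensemble's random seed with early stopping (50 rounds) on validation, and
the best validation run wins; ties keep the lower seed. Desk defaults are
20 trials / 10 seeds (full scale: 100/100). Missing feature cells (e.g.
failed waveform QC) ride LightGBM's native missing-value routing; rows
are never dropped for missing engineered features.

## Evaluation

* **AUROC** is the Mann–Whitney rank statistic with average ranks (ties
  count 1/2); **AUPRC** is average precision. Both verified against
  exhaustive pair enumeration.
* **Bootstrap**: percentile CIs (assumption-free, matching the
  non-parametric intent); replicates drawing a single class are redrawn.
  Deltas between two score vectors are computed on the *same* resample
  indices (paired); an independent-resample mode is a one-line variant.
  Desk default 2000 replicates, full scale 10000. Measured coverage for
  a population AUROC of 0.75 (bi-normal scores, n=180) is ≈ 93–95 %.
* **Operating points**: among thresholds with validation sensitivity ≥
  0.85, the one maximizing specificity, ties broken toward higher
  sensitivity; test-set sensitivity/specificity/PPV/NPV carry bootstrap
  CIs at that frozen threshold.
* **Calibration**: equal-count prediction quintiles (stable sort by score
  then position) with mean predicted vs observed event fraction, plus an
  isotonic map fit on validation and applied to test.
* **Attribution**: exact tree-path Shapley values from the fitted
  ensemble (`pred_contrib`); a feature's contribution is its mean |SHAP|
  normalized to sum to 100 %; direction is the Pearson correlation
  between feature values and SHAP values (missing for zero variance).
* **Reclassification**: visits correct under the rich model and wrong
  under the triage baseline at the 0.85-validation-sensitivity operating
  points, split by direction; mean feature differences are scaled by the
  non-reclassified SD with Welch two-sided t-tests. Empty cohorts yield
  empty tables, not errors.
* **MEWS alignment**: of visits reaching MEWS ≥ 4 in the window, the
  proportion predicted to decompensate; of visits with max MEWS < 4, the
  proportion predicted negative; undefined proportions are reported
  missing.

## Problem sizes

The test suite and `scripts/acceptance.py` run everything at desk scale,
chosen as the package's standard working sizes: 4000-visit cohorts for the
ablation experiment (8 tuning trials, 3 ensemble seeds, 5 training seeds),
1000 random series for HRV oracle agreement, 200 Monte-Carlo repetitions ×
400 bootstrap replicates for CI coverage, and 2000 bootstrap replicates
for reported CIs. Full-scale settings (100 trials/seeds, 10000
replicates, 60 encoder epochs) are plain configuration changes.

## Known limitations

* Frequency-domain HRV from the ECG signal PSD is nonstandard; its band
  powers reflect beat morphology as much as autonomic variability. Both
  substrates are provided precisely because the choice matters.
* The synthetic PPG has no dicrotic notch, venous modulation or motion
  artifact spectrum; PPG quality thresholds tuned here may not transfer
  to device data.
* The ablation experiment demonstrates *qualitative* signal recovery
  (monitoring features beat triage-only); its AUROC magnitudes are
  properties of the simulator's effect sizes, not estimates of clinical
  performance.
* MEWS ≥ 4 prevalence is emergent from the simulator rather than
  configured, and is low; mews4 models at small n can be single-class
  and are refused rather than silently fit.
* The encoder is deliberately small; it shows gradient-clean training and
  morphology-sensitive embeddings, not state-of-the-art waveform
  representation learning.
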