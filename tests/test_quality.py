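"""R-peak detection accuracy and ECG/PPG quality gating."""

import numpy as np
import pytest

from edecomp.quality import (
    QCThresholds,
    assess_ecg_quality,
    assess_ppg_quality,
    detect_r_peaks,
    filter_ecg,
    preprocess_and_select_window,
)
from edecomp.synth import (
    ArtifactSpec,
    generate_rr_series,
    synthesize_waveform_pair,
)
from edecomp.types import RRGroundTruth, WaveformSegment


def _pair_at(hr, duration=60.0, seed=0, **kw):
    rr = generate_rr_series(hr, duration=duration, seed=seed)
    return rr, synthesize_waveform_pair(rr, pat=min(0.25, 30.0 / hr), **kw)


class TestDetector:
    def test_sixty_bpm_count_and_timing(self):
        rr, (ecg, _) = _pair_at(60, duration=60)
        peaks, _ = detect_r_peaks(ecg)
        assert abs(len(peaks) - 60) <= 1
        truth = rr.beat_times[: len(peaks)]
        err_ms = np.abs(peaks / ecg.fs - truth) * 1000
        assert err_ms.max() <= 10.0

    @pytest.mark.parametrize("hr", [50, 75, 120])
    def test_rr_matches_truth_within_one_raw_sample(self, hr):
        rr = generate_rr_series(hr, 20, 15, 8, duration=60, seed=hr)
        ecg, _ = synthesize_waveform_pair(rr, pat=0.2, seed=hr)
        peaks, rr_ms = detect_r_peaks(ecg)
        assert len(peaks) == len(rr.beat_times)
        # each beat located within one raw sample; intervals (a difference
        # of two beat times) therefore within two
        one_sample_ms = 1000.0 / ecg.fs
        beat_err = np.abs(peaks / ecg.fs - rr.beat_times) * 1000
        assert beat_err.max() <= one_sample_ms + 1e-9
        assert np.max(np.abs(rr_ms - rr.rr_intervals)) <= 2 * one_sample_ms + 1e-9

    def test_fast_rate_heart_rate_estimate(self):
        _, (ecg, _) = _pair_at(180, duration=60)
        _, rr_ms = detect_r_peaks(ecg)
        hr = 60000.0 / rr_ms.mean()
        assert abs(hr - 180) < 2.0

    def test_zero_signal_yields_no_peaks(self):
        flat = WaveformSegment("ecg", 500.0, np.zeros(5000))
        peaks, rr_ms = detect_r_peaks(flat)
        assert len(peaks) == 0 and len(rr_ms) == 0

    def test_non_ecg_rejected(self):
        ppg = WaveformSegment("ppg", 125.0, np.ones(1000))
        with pytest.raises(ValueError):
            detect_r_peaks(ppg)


class TestECGGate:
    def test_clean_segment_passes(self):
        _, (ecg, _) = _pair_at(72, seed=2)
        rep = assess_ecg_quality(ecg.slice(0, 60))
        assert rep.passed and abs(rep.detected_hr - 72) < 2

    def test_slow_beat_train_fails_hr_range(self):
        beats = np.arange(0.0, 62.0, 3.0)  # 20 bpm
        rr = RRGroundTruth(beats, np.diff(beats) * 1000, 20.0, 0.0, 0.0, 0.0)
        ecg, _ = synthesize_waveform_pair(rr, pat=0.25)
        rep = assess_ecg_quality(ecg.slice(0, 60))
        assert "HR_RANGE" in rep.reasons and not rep.passed

    def test_large_spike_fails_amplitude(self):
        _, (ecg, _) = _pair_at(
            72, seed=2, artifact_spec=ArtifactSpec(spikes=[(10.0, 5.0)])
        )
        assert "AMPLITUDE" in assess_ecg_quality(ecg.slice(0, 60)).reasons


class TestPPGGate:
    def test_clean_segment_passes(self, clean_pair):
        _, ppg = clean_pair
        assert assess_ppg_quality(ppg.slice(0, 60)).passed

    def test_flatline_fails_stationary(self, clean_rr):
        art = ArtifactSpec(flatlines=[(20.0, 20.0, "ppg")])
        _, ppg = synthesize_waveform_pair(clean_rr, 0.25, 2.0, art, seed=3)
        assert "STATIONARY" in assess_ppg_quality(ppg.slice(0, 60)).reasons

    def test_inverted_signal_fails_skewness(self, clean_pair):
        _, ppg = clean_pair
        inv = WaveformSegment("ppg", ppg.fs, -ppg.samples[: 125 * 60])
        assert "SKEWNESS" in assess_ppg_quality(inv).reasons

    def test_artifact_never_clears_a_failing_reason(self, clean_rr):
        # monotonicity: piling a second artifact on keeps the first reason
        art1 = ArtifactSpec(flatlines=[(20.0, 20.0, "ppg")])
        _, p1 = synthesize_waveform_pair(clean_rr, 0.25, 2.0, art1, seed=3)
        art2 = ArtifactSpec(
            flatlines=[(20.0, 20.0, "ppg")], dropouts=[(45.0, 10.0, "ppg")]
        )
        _, p2 = synthesize_waveform_pair(clean_rr, 0.25, 2.0, art2, seed=3)
        r1 = set(assess_ppg_quality(p1.slice(0, 60)).reasons)
        r2 = set(assess_ppg_quality(p2.slice(0, 60)).reasons)
        assert r1 <= r2


class TestWindowSelection:
    def _long_pair(self, artifact=None, minutes=3):
        rr = generate_rr_series(72, 25, 15, 8, duration=minutes * 60, seed=9)
        return synthesize_waveform_pair(rr, 0.25, 2.0, artifact, seed=9)

    def test_clean_streams_select_first_window(self):
        ecg, ppg = self._long_pair()
        sel = preprocess_and_select_window(ecg, ppg, assessment_minutes=3)
        assert sel is not None and sel.start_s == 0.0
        assert sel.ecg.fs == 125.0 and sel.ppg.fs == 125.0

    def test_corrupt_first_window_selects_second(self):
        art = ArtifactSpec(spikes=[(10.0, 5.0)])
        ecg, ppg = self._long_pair(artifact=art)
        sel = preprocess_and_select_window(ecg, ppg, assessment_minutes=3)
        assert sel is not None and sel.start_s == 60.0

    def test_persistent_artifacts_exclude_visit(self):
        art = ArtifactSpec(
            spikes=[(t, 5.0) for t in np.arange(5.0, 175.0, 15.0)]
        )
        ecg, ppg = self._long_pair(artifact=art)
        assert preprocess_and_select_window(ecg, ppg, assessment_minutes=3) is None

    def test_short_streams_rejected(self):
        rr = generate_rr_series(70, duration=30, seed=0)
        ecg, ppg = synthesize_waveform_pair(rr, 0.25)
        with pytest.raises(ValueError):
            preprocess_and_select_window(ecg, ppg, assessment_minutes=0.5)


class TestFiltering:
    def test_decimation_length_exact(self):
        for n in (30000, 30001, 30003):
            ecg = WaveformSegment("ecg", 500.0, np.random.default_rng(0).normal(size=n))
            out = filter_ecg(ecg)
            assert len(out.samples) == int(np.ceil(n / 4))

    def test_passband_tone_preserved(self):
        t = np.arange(0, 60, 1 / 500)
        for f in (5.0, 20.0, 30.0):
            tone = WaveformSegment("ecg", 500.0, np.sin(2 * np.pi * f * t))
            out = filter_ecg(tone)
            # amplitude retained within filter droop (zero-phase squares
            # the Butterworth magnitude, so the band edge itself sags)
            assert np.percentile(np.abs(out.samples), 99) > 0.8

    def test_stopband_tone_suppressed(self):
        t = np.arange(0, 60, 1 / 500)
        tone = WaveformSegment("ecg", 500.0, np.sin(2 * np.pi * 60.0 * t))
        out = filter_ecg(tone)
        assert np.percentile(np.abs(out.samples), 99) < 0.2

    def test_threshold_invariants(self):
        with pytest.raises(ValueError):
            QCThresholds(hr_min=300, hr_max=25)
        with pytest.raises(ValueError):
            QCThresholds(target_fs=130.0)
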