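"""Simulator contracts: determinism, prevalence control, signal ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from edecomp.synth import (
    ArtifactSpec,
    SimConfig,
    generate_cohort,
    generate_rr_series,
    generate_vitals_stream,
    synthesize_waveform_pair,
)
from edecomp.types import SimulationError


class TestRRSeries:
    def test_constant_series_without_modulation(self):
        rr = generate_rr_series(mean_hr=60, duration=60, seed=0)
        assert np.allclose(rr.rr_intervals, 1000.0)
        assert len(rr.beat_times) in (60, 61)

    def test_noise_sd_recovered(self):
        rr = generate_rr_series(60, 0, 0, noise_sd=20, duration=300, seed=3)
        sd = np.std(rr.rr_intervals, ddof=1)
        assert abs(sd - 20.0) / 20.0 < 0.25

    def test_hf_modulation_peaks_at_quarter_hz(self):
        rr = generate_rr_series(70, 0, hf_amplitude=30, duration=300, seed=4)
        # evenly resample the tachogram and locate its spectral peak
        t = rr.beat_times[1:]
        grid = np.arange(t[0], t[-1], 0.25)
        tach = np.interp(grid, t, rr.rr_intervals)
        f, p = sps.periodogram(tach - tach.mean(), fs=4.0)
        assert abs(f[np.argmax(p)] - 0.25) < 0.02

    def test_invalid_parameters_raise(self):
        with pytest.raises(SimulationError):
            generate_rr_series(mean_hr=20, duration=60)
        with pytest.raises(SimulationError):
            generate_rr_series(mean_hr=200, lf_amplitude=400, duration=60)

    @given(
        mean_hr=st.floats(40, 180),
        noise=st.floats(0, 40),
        seed=st.integers(0, 2**20),
    )
    @settings(max_examples=25, deadline=None)
    def test_intervals_positive_and_consistent(self, mean_hr, noise, seed):
        rr = generate_rr_series(mean_hr, 10, 10, noise, duration=30, seed=seed)
        assert np.all(rr.rr_intervals > 0)
        assert np.allclose(np.diff(rr.beat_times) * 1000, rr.rr_intervals)


class TestWaveformPair:
    def test_spike_injection_contract(self, clean_rr):
        art = ArtifactSpec(spikes=[(10.0, 5.0)])
        ecg, _ = synthesize_waveform_pair(clean_rr, 0.25, 2.0, art, seed=1)
        window = ecg.samples[int(9.5 * 500) : int(10.5 * 500)]
        assert np.max(np.abs(window)) > 4.0

    def test_perfusion_index_sets_ac_dc_ratio(self):
        rr = generate_rr_series(60, duration=10, seed=0)
        _, ppg = synthesize_waveform_pair(rr, 0.25, perfusion_index=2.0, seed=0)
        beat = ppg.samples[3 * 125 : 4 * 125]
        ratio = (beat.max() - beat.min()) / beat.mean()
        assert abs(ratio - 0.02) / 0.02 < 0.10

    def test_pat_exceeding_shortest_rr_rejected(self, clean_rr):
        with pytest.raises(SimulationError):
            synthesize_waveform_pair(clean_rr, pat=2.0)

    def test_sampling_rates(self, clean_pair):
        ecg, ppg = clean_pair
        assert ecg.fs == 500.0 and ppg.fs == 125.0


class TestVitalsStream:
    def test_identity_without_noise_or_slopes(self):
        st_ = generate_vitals_stream(duration=1800, seed=0)
        assert np.allclose(st_.hr, 80.0) and np.allclose(st_.spo2, 98.0)

    def test_trend_slope_recovered_by_regression(self):
        st_ = generate_vitals_stream(
            baselines={"hr": 80}, slopes={"hr": 1.0},
            noise={"hr": 0.5}, duration=1800, seed=2,
        )
        mins = st_.hr[:900].reshape(15, 60).mean(axis=1)
        slope = np.polyfit(np.arange(15), mins, 1)[0]
        assert abs(slope - 1.0) < 0.1

    def test_hypoxia_onset_contract(self):
        st_ = generate_vitals_stream(
            onsets={"hypoxia": 35.0}, duration=8100, seed=3,
            noise={"spo2": 0.4},
        )
        post = st_.spo2[15 * 60 : 75 * 60]
        assert post.min() < 90.0

    def test_onset_holds_beyond_threshold(self):
        st_ = generate_vitals_stream(
            onsets={"tachycardia": 10.0}, duration=8100, seed=4,
            noise={"hr": 1.5},
        )
        onset_i = (15 + 10) * 60 + 60  # after the one-minute ramp
        assert np.all(st_.hr[onset_i : onset_i + 120] > 110.0)

    def test_stable_assessment_flag_rejects_early_onset(self):
        with pytest.raises(SimulationError):
            generate_vitals_stream(
                onsets={"tachycardia": -5.0}, duration=8100,
                stable_assessment=True,
            )

    def test_intermittent_channels_default_half_hour(self):
        st_ = generate_vitals_stream(duration=7200, seed=0)
        assert np.allclose(np.diff(st_.sbp_times), 1800.0)


class TestCohort:
    def test_same_seed_identical_cohorts(self, small_cohort):
        other = generate_cohort(SimConfig(n_visits=200, seed=5))
        assert small_cohort.triage.equals(other.triage)
        assert small_cohort.ground_truth.equals(other.ground_truth)
        vid = small_cohort.visit_ids[7]
        assert np.array_equal(small_cohort.vitals[vid].hr, other.vitals[vid].hr)
        assert np.array_equal(
            small_cohort.rr_truth[vid].beat_times, other.rr_truth[vid].beat_times
        )

    def test_different_seed_differs(self, small_cohort):
        other = generate_cohort(SimConfig(n_visits=200, seed=99))
        assert not small_cohort.triage.equals(other.triage)

    def test_zero_prevalence_yields_no_events(self):
        cfg = SimConfig(
            n_visits=150, seed=1,
            prevalence={"tachycardia": 0.0, "hypoxia": 0.1, "hypotension": 0.02},
        )
        c = generate_cohort(cfg)
        assert not c.ground_truth["event_tachycardia"].any()

    def test_prevalence_within_three_binomial_sd(self):
        p = 0.06
        n = 2000
        c = generate_cohort(
            SimConfig(n_visits=n, seed=1, prevalence={
                "tachycardia": p, "hypoxia": 0.112, "hypotension": 0.023})
        )
        frac = c.ground_truth["event_tachycardia"].mean()
        sd = np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 3 * sd

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_visits=0)
        with pytest.raises(ValueError):
            SimConfig(prevalence={"tachycardia": 1.5})

    def test_triage_map_identity(self, small_cohort):
        t = small_cohort.triage
        assert np.allclose(t["map"], t["sbp"] / 3 + 2 * t["dbp"] / 3, atol=0.1)

    def test_violators_present_when_requested(self):
        c = generate_cohort(SimConfig(n_visits=100, seed=2, violator_fraction=0.1))
        gt = c.ground_truth
        viol = c.triage.loc[gt["is_violator"].values, "hr"]
        assert len(viol) == 10 and (viol > 110).all()
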