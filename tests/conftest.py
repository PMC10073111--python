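import numpy as np
import pytest

from edecomp.synth import (
    SimConfig,
    generate_cohort,
    generate_rr_series,
    synthesize_waveform_pair,
)


@pytest.fixture(scope="session")
def clean_rr():
    """90 s of beats at 72 bpm with moderate LF/HF modulation and noise."""
    return generate_rr_series(
        mean_hr=72, lf_amplitude=30, hf_amplitude=20, noise_sd=10,
        duration=90, seed=11,
    )


@pytest.fixture(scope="session")
def clean_pair(clean_rr):
    """A clean coupled ECG/PPG pair with PAT 0.25 s and PI 2.0 %."""
    return synthesize_waveform_pair(
        clean_rr, pat=0.25, perfusion_index=2.0, seed=12
    )


@pytest.fixture(scope="session")
def small_cohort():
    """200 visits without rendered waveforms (beat-train HRV path)."""
    return generate_cohort(SimConfig(n_visits=200, seed=5))


@pytest.fixture(scope="session")
def wave_cohort():
    """30 visits with rendered 90-s waveform pairs."""
    return generate_cohort(
        SimConfig(n_visits=30, seed=6, waveforms="window", artifact_rate=0.2)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
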