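"""Core domain containers shared across the pipeline.

Conventions used throughout the package:

* Time within a visit is measured in seconds from *rooming* (t = 0), the
  moment continuous monitoring starts.  The assessment period is the first
  ``assessment_minutes`` (default 15) of monitoring; prediction windows are
  measured from the end of the assessment period.
* Arrival times across visits are hours from the start of the study period.
* Continuous monitor channels are sampled at 1 Hz; missing samples are NaN.
* RR intervals (the beat-to-beat interval of the ECG, not respiratory rate)
  are in milliseconds; beat times in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "TriageRecord",
    "VitalStream",
    "WaveformSegment",
    "RRGroundTruth",
    "Visit",
    "SimulationError",
]


class SimulationError(ValueError):
    """Raised when simulator parameters cannot produce a valid signal."""


@dataclass
class TriageRecord:
    """Per-visit demographics, acuity and triage vital signs.

    ``map`` must satisfy the arterial-pressure identity
    MAP = SBP/3 + 2*DBP/3 (checked to 0.1 mmHg on construction).
    """

    visit_id: str
    patient_id: str
    arrival_time: float  # hours from study start
    age: float  # years
    gender: str  # "F" | "M"
    esi: int  # Emergency Severity Index, 1 (most acute) .. 5
    cc_category: int  # chief-complaint category, 1..46
    hr: float  # bpm
    rr: float  # breaths/min
    spo2: float  # %
    sbp: float  # mmHg
    dbp: float  # mmHg
    map: float  # mmHg
    temperature: float  # degrees C

    def __post_init__(self) -> None:
        if not 1 <= self.esi <= 5:
            raise ValueError(f"ESI must be in 1..5, got {self.esi}")
        expected_map = self.sbp / 3.0 + 2.0 * self.dbp / 3.0
        if abs(self.map - expected_map) > 0.1:
            raise ValueError(
                f"MAP {self.map:.2f} inconsistent with SBP/DBP "
                f"(expected {expected_map:.2f})"
            )


@dataclass
class VitalStream:
    """1-Hz numeric monitor channels for one visit, t = 0 at rooming.

    Continuous channels (``hr``, ``rr``, ``spo2``, ``map``, ``rr_interval``,
    ``perfusion_index``) are equal-length float arrays sampled every second;
    NaN marks a missing sample.  Blood pressure and temperature are charted
    intermittently and stored as (times, values) pairs, to be carried
    forward by consumers.
    """

    hr: np.ndarray  # bpm
    rr: np.ndarray  # breaths/min
    spo2: np.ndarray  # %
    map: np.ndarray  # mmHg
    rr_interval: np.ndarray  # ms, beat-to-beat
    perfusion_index: np.ndarray  # %
    sbp_times: np.ndarray  # s
    sbp_values: np.ndarray  # mmHg
    dbp_times: np.ndarray  # s
    dbp_values: np.ndarray  # mmHg
    temperature_times: np.ndarray  # s
    temperature_values: np.ndarray  # degrees C

    def __post_init__(self) -> None:
        n = len(self.hr)
        for name in ("rr", "spo2", "map", "rr_interval", "perfusion_index"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name!r} length mismatch")

    @property
    def duration_s(self) -> int:
        return len(self.hr)


ECG_FS = 500.0
PPG_FS = 125.0


@dataclass
class WaveformSegment:
    """A sampled ECG or PPG trace.

    ECG amplitudes are in mV; PPG amplitudes are in arbitrary units
    (monitor photoplethysmography output has no calibrated unit).
    """

    modality: str  # "ecg" | "ppg"
    fs: float  # Hz
    samples: np.ndarray
    start_time: float = 0.0  # seconds from rooming

    def __post_init__(self) -> None:
        if self.modality not in ("ecg", "ppg"):
            raise ValueError(f"unknown modality {self.modality!r}")
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    def slice(self, t0: float, t1: float) -> "WaveformSegment":
        """Sub-segment covering [t0, t1) seconds relative to segment start."""
        i0 = int(round(t0 * self.fs))
        i1 = int(round(t1 * self.fs))
        return WaveformSegment(
            modality=self.modality,
            fs=self.fs,
            samples=self.samples[i0:i1],
            start_time=self.start_time + t0,
        )


@dataclass
class RRGroundTruth:
    """Known beat times and RR intervals used to seed waveform synthesis.

    ``rr_intervals`` are the successive differences of ``beat_times`` in ms;
    the target_* fields record the generator parameters so downstream HRV
    estimates can be validated against the truth.
    """

    beat_times: np.ndarray  # s
    rr_intervals: np.ndarray  # ms
    target_mean_hr: float  # bpm
    target_sdrr: float  # ms (SD implied by the generator parameters)
    lf_amplitude: float  # ms, 0.1 Hz modulation depth
    hf_amplitude: float  # ms, 0.25 Hz modulation depth

    def __post_init__(self) -> None:
        if np.any(self.rr_intervals <= 0):
            raise SimulationError("RR intervals must be positive")
        diffs = np.diff(self.beat_times) * 1000.0
        if len(diffs) != len(self.rr_intervals) or not np.allclose(
            diffs, self.rr_intervals, atol=1e-6
        ):
            raise ValueError("rr_intervals must equal diff(beat_times) in ms")


@dataclass
class Visit:
    """Everything observed for one synthetic ED visit."""

    triage: TriageRecord
    vitals: Optional[VitalStream] = None
    ecg: Optional[WaveformSegment] = None
    ppg: Optional[WaveformSegment] = None
    rr_truth: Optional[RRGroundTruth] = None
    ground_truth: dict = field(default_factory=dict)
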