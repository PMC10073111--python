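"""Synthetic ED monitoring cohorts with known physiologic ground truth.

The generator emulates the three data sources consumed by the pipeline:

1. per-visit triage records (demographics, acuity, chief complaint, vitals),
2. 1-Hz numeric monitor channels with decompensation dynamics, intermittent
   blood pressure / temperature charting, and
3. coupled ECG (500 Hz) / PPG (125 Hz) waveform pairs built from a common
   beat train, with controllable heart-rate variability, pulse arrival time
   and perfusion index, plus injectable recording artifacts.

Decompensation outcomes (tachycardia HR > 110 bpm, hypoxia SpO2 < 90 %,
hypotension MAP < 65 mmHg) are driven by a shared latent risk: the latent
also tilts vital-sign trend slopes, lowers RR-interval variability (SDRR)
and lowers the PPG perfusion index, so that downstream models have a
recoverable multi-channel signal.  Every random draw is controlled by the
top-level seed; identical configurations produce identical cohorts.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    ECG_FS,
    PPG_FS,
    RRGroundTruth,
    SimulationError,
    TriageRecord,
    VitalStream,
    WaveformSegment,
)

__all__ = [
    "SimConfig",
    "ArtifactSpec",
    "Cohort",
    "generate_rr_series",
    "synthesize_waveform_pair",
    "generate_vitals_stream",
    "generate_cohort",
]

OUTCOMES = ("tachycardia", "hypoxia", "hypotension")

#: decompensation thresholds (strict crossings define events)
THRESHOLDS = {"tachycardia": 110.0, "hypoxia": 90.0, "hypotension": 65.0}
#: channel carrying each outcome and the direction of the abnormal crossing
OUTCOME_CHANNEL = {
    "tachycardia": ("hr", +1),
    "hypoxia": ("spo2", -1),
    "hypotension": ("map", -1),
}


@dataclass
class SimConfig:
    """Study-shape constants and effect sizes for cohort simulation.

    Default outcome prevalences are the incidences of a stable adult ED
    cohort (tachycardia ~6.1 %, hypoxia ~11.2 %, hypotension ~2.3 %);
    events occur within ``follow_minutes`` after the assessment period.
    Effect sizes link a standard-normal latent risk to the observable
    signal: trend slopes during assessment (units/min per risk SD),
    a multiplicative reduction in SDRR, and a multiplicative reduction
    in perfusion index.
    """

    n_visits: int = 200
    seed: int = 0
    prevalence: dict = field(
        default_factory=lambda: {
            "tachycardia": 0.0611,
            "hypoxia": 0.1120,
            "hypotension": 0.0233,
        }
    )
    assessment_minutes: int = 15
    follow_minutes: int = 120
    # latent-risk effect sizes
    slope_effect_hr: float = 0.25  # bpm/min per risk SD
    slope_effect_spo2: float = 0.05  # %/min per risk SD
    slope_effect_map: float = 0.20  # mmHg/min per risk SD
    hrv_effect: float = 0.35  # log-scale SDRR reduction per risk SD
    perfusion_effect: float = 0.35  # log-scale PI reduction per risk SD
    risk_share: float = 0.7  # corr. of each outcome's risk with shared latent
    # measurement noise (1-Hz channels)
    noise: dict = field(
        default_factory=lambda: {
            "hr": 1.5, "rr": 1.0, "spo2": 0.5, "map": 2.0,
        }
    )
    artifact_rate: float = 0.0  # fraction of visits with a corrupt first window
    violator_fraction: float = 0.0  # fraction violating inclusion at triage
    intermittent_minutes: float = 30.0  # BP/temperature charting interval
    n_cc_categories: int = 46
    waveforms: str = "none"  # "none" | "window" | "assessment"

    def __post_init__(self) -> None:
        if self.n_visits < 1:
            raise ValueError("n_visits must be >= 1")
        if self.assessment_minutes <= 0:
            raise ValueError("assessment_minutes must be positive")
        for k, p in self.prevalence.items():
            if not 0.0 <= p < 1.0:
                raise ValueError(f"prevalence[{k!r}]={p} outside [0, 1)")


@dataclass
class ArtifactSpec:
    """Recording artifacts to inject into a waveform pair.

    ``spikes``: (time_s, amplitude_mV) added to the ECG.
    ``flatlines``: (start_s, duration_s, target) windows where the signal
    holds its value at the window start; target in {"ecg", "ppg", "both"}.
    ``dropouts``: (start_s, duration_s, target) windows where the signal
    drops to its resting level (0 mV for ECG, the DC level for PPG).
    """

    spikes: list = field(default_factory=list)
    flatlines: list = field(default_factory=list)
    dropouts: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# RR-interval (beat train) generation
# ---------------------------------------------------------------------------

RR_FLOOR_MS = 200.0
LF_FREQ = 0.10  # Hz, centre of the low-frequency HRV band
HF_FREQ = 0.25  # Hz, centre of the high-frequency (respiratory) band


def generate_rr_series(
    mean_hr: float,
    lf_amplitude: float = 0.0,
    hf_amplitude: float = 0.0,
    noise_sd: float = 0.0,
    duration: float = 60.0,
    seed: int | np.random.Generator = 0,
) -> RRGroundTruth:
    """Generate a beat train with sinusoidal LF/HF modulation of RR.

    RR(t) = 60000/mean_hr + lf·sin(2π·0.1·t) + hf·sin(2π·0.25·t) + ε,
    ε ~ N(0, noise_sd²), clipped at a 200 ms physiologic floor.  The
    implied interval SD (recorded as ``target_sdrr``) is
    sqrt(lf²/2 + hf²/2 + noise_sd²).
    """
    if not 25.0 < mean_hr < 300.0:
        raise SimulationError(f"mean_hr {mean_hr} outside (25, 300) bpm")
    if duration <= 0:
        raise SimulationError("duration must be positive")
    base = 60000.0 / mean_hr
    if base - lf_amplitude - hf_amplitude <= 0:
        raise SimulationError("modulation amplitudes exceed the base interval")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    beats = [0.0]
    t = 0.0
    while True:
        rr = (
            base
            + lf_amplitude * math.sin(2 * math.pi * LF_FREQ * t)
            + hf_amplitude * math.sin(2 * math.pi * HF_FREQ * t)
            + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        )
        rr = max(rr, RR_FLOOR_MS)
        t += rr / 1000.0
        if t > duration:
            break
        beats.append(t)
    beat_times = np.asarray(beats)
    if len(beat_times) < 2:
        raise SimulationError("duration too short to place two beats")
    rr_ms = np.diff(beat_times) * 1000.0
    target_sdrr = math.sqrt(
        lf_amplitude**2 / 2 + hf_amplitude**2 / 2 + noise_sd**2
    )
    return RRGroundTruth(
        beat_times=beat_times,
        rr_intervals=rr_ms,
        target_mean_hr=mean_hr,
        target_sdrr=target_sdrr,
        lf_amplitude=lf_amplitude,
        hf_amplitude=hf_amplitude,
    )


# ---------------------------------------------------------------------------
# ECG / PPG waveform synthesis
# ---------------------------------------------------------------------------

#: static sum-of-Gaussians beat template: (offset s, amplitude mV, width s)
ECG_TEMPLATE = (
    (-0.200, 0.12, 0.022),  # P
    (-0.028, -0.08, 0.010),  # Q
    (0.000, 1.00, 0.010),  # R
    (0.030, -0.12, 0.010),  # S
    (0.260, 0.25, 0.045),  # T
)

PPG_RISE_S = 0.08  # systolic upstroke width at a 1-s beat
PPG_FALL_S = 0.19  # diastolic decay width at a 1-s beat
PPG_DC = 1.0  # arbitrary-unit DC level of the pulse oximeter signal


def _add_pulses(t: np.ndarray, centers: np.ndarray, shape_fn, half_width: float,
                out: np.ndarray) -> None:
    """Accumulate a per-beat pulse shape into ``out`` using local windows."""
    fs = 1.0 / (t[1] - t[0])
    n = len(t)
    for c in centers:
        i0 = max(0, int((c - half_width) * fs))
        i1 = min(n, int((c + half_width) * fs) + 1)
        if i0 >= i1:
            continue
        out[i0:i1] += shape_fn(t[i0:i1] - c)


def synthesize_waveform_pair(
    rr: RRGroundTruth,
    pat: float = 0.25,
    perfusion_index: float = 1.5,
    artifact_spec: Optional[ArtifactSpec] = None,
    seed: int | np.random.Generator = 0,
    duration: Optional[float] = None,
    baseline_noise_mv: float = 0.004,
) -> tuple[WaveformSegment, WaveformSegment]:
    """Render a coupled ECG (500 Hz) / PPG (125 Hz) pair from a beat train.

    ECG beats are a static sum-of-Gaussians template (unambiguous ~1 mV
    R-peaks) placed at the beat times.  The PPG is a smooth pulse wave whose
    systolic peaks lag the R-peaks by exactly ``pat`` seconds and whose
    AC/DC amplitude ratio equals ``perfusion_index``/100.
    """
    if perfusion_index <= 0:
        raise SimulationError("perfusion_index must be positive")
    min_rr_s = float(np.min(rr.rr_intervals)) / 1000.0
    if not 0.0 < pat < min_rr_s:
        raise SimulationError(
            f"pat {pat} s must lie in (0, shortest RR {min_rr_s:.3f} s)"
        )
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    if duration is None:
        duration = float(rr.beat_times[-1]) + min_rr_s
    n_ecg = int(round(duration * ECG_FS))
    n_ppg = int(round(duration * PPG_FS))
    t_ecg = np.arange(n_ecg) / ECG_FS
    t_ppg = np.arange(n_ppg) / PPG_FS

    ecg = np.zeros(n_ecg)
    for offset, amp, width in ECG_TEMPLATE:
        _add_pulses(
            t_ecg,
            rr.beat_times + offset,
            lambda d, a=amp, w=width: a * np.exp(-(d**2) / (2 * w**2)),
            5 * width,
            ecg,
        )
    if baseline_noise_mv > 0:
        ecg += rng.normal(0.0, baseline_noise_mv, n_ecg)

    # asymmetric pulse with its maximum exactly at the beat time + pat;
    # widths shrink with the beat interval (faster rates -> narrower pulses,
    # keeping the waveform positively skewed rather than sinusoidal)
    scale = float(np.clip(np.mean(rr.rr_intervals) / 1000.0, 0.5, 1.2))
    rise = PPG_RISE_S * scale
    fall = PPG_FALL_S * scale

    def _pulse(d: np.ndarray) -> np.ndarray:
        out = np.empty_like(d)
        neg = d < 0
        out[neg] = np.exp(-(d[neg] ** 2) / (2 * rise**2))
        out[~neg] = np.exp(-(d[~neg] ** 2) / (2 * fall**2))
        return out

    pulses = np.zeros(n_ppg)
    _add_pulses(t_ppg, rr.beat_times + pat, _pulse, 1.0, pulses)
    ac = perfusion_index / 100.0 * PPG_DC
    ppg = PPG_DC + ac * (pulses - pulses.mean())
    ppg += rng.normal(0.0, 0.002 * ac, n_ppg)

    if artifact_spec is not None:
        _inject_artifacts(ecg, ECG_FS, ppg, PPG_FS, artifact_spec)

    return (
        WaveformSegment("ecg", ECG_FS, ecg),
        WaveformSegment("ppg", PPG_FS, ppg),
    )


def _inject_artifacts(ecg: np.ndarray, ecg_fs: float, ppg: np.ndarray,
                      ppg_fs: float, spec: ArtifactSpec) -> None:
    for t0, amp in spec.spikes:
        i = int(round(t0 * ecg_fs))
        if 0 <= i < len(ecg):
            j = min(len(ecg), i + max(1, int(0.01 * ecg_fs)))
            ecg[i:j] = amp
    for start, dur, target in spec.flatlines:
        for sig, fs in _targets(target, ecg, ecg_fs, ppg, ppg_fs):
            i0 = int(round(start * fs))
            i1 = min(len(sig), int(round((start + dur) * fs)))
            if 0 <= i0 < len(sig):
                sig[i0:i1] = sig[i0]
    for start, dur, target in spec.dropouts:
        for sig, fs in _targets(target, ecg, ecg_fs, ppg, ppg_fs):
            i0 = int(round(start * fs))
            i1 = min(len(sig), int(round((start + dur) * fs)))
            sig[i0:i1] = 0.0 if sig is ecg else PPG_DC


def _targets(target, ecg, ecg_fs, ppg, ppg_fs):
    if target in ("ecg", "both"):
        yield ecg, ecg_fs
    if target in ("ppg", "both"):
        yield ppg, ppg_fs


# ---------------------------------------------------------------------------
# 1-Hz vitals stream
# ---------------------------------------------------------------------------

DEFAULT_BASELINES = {
    "hr": 80.0, "rr": 16.0, "spo2": 98.0, "map": 90.0,
    "perfusion_index": 1.5, "sbp": 130.0, "dbp": 75.0, "temperature": 36.9,
}

PHYSIO_CLIP = {
    "hr": (20.0, 250.0), "rr": (4.0, 60.0), "spo2": (40.0, 100.0),
    "map": (20.0, 200.0), "perfusion_index": (0.02, 20.0),
}

#: post-onset plateau placed beyond each outcome threshold, and the clip
#: that keeps noisy samples strictly beyond it
ONSET_PLATEAU = {
    "tachycardia": (116.0, 112.0, +1),
    "hypoxia": (85.0, 88.5, -1),
    "hypotension": (58.0, 63.0, -1),
}

TREND_DECAY_MIN = 10.0  # e-folding of assessment trends after assessment


def generate_vitals_stream(
    baselines: Optional[dict] = None,
    slopes: Optional[dict] = None,
    onsets: Optional[dict] = None,
    noise: Optional[dict] = None,
    duration: float = 8100.0,
    seed: int | np.random.Generator = 0,
    assessment_minutes: float = 15.0,
    intermittent_minutes: float = 30.0,
    stable_assessment: bool = False,
    onset_extremity: Optional[dict] = None,
    missing_fraction: float = 0.0,
) -> VitalStream:
    """Simulate 1-Hz monitor channels for one visit.

    Channels follow baseline + slope·t + Gaussian noise during the
    assessment period; the linear trend then relaxes (10-min e-folding) so
    uneventful visits stay near baseline.  ``onsets`` maps outcome name to
    the onset time in minutes *after* the assessment period; from onset to
    the end of the record the outcome's channel ramps (60 s) to a plateau
    beyond its threshold and is clipped to stay there.  SBP/DBP/temperature
    are emitted intermittently (default every 30 min).  Slopes are in
    units/minute.
    """
    baselines = {**DEFAULT_BASELINES, **(baselines or {})}
    slopes = slopes or {}
    onsets = {k: v for k, v in (onsets or {}).items() if v is not None}
    noise = {**{"hr": 0.0, "rr": 0.0, "spo2": 0.0, "map": 0.0}, **(noise or {})}
    onset_extremity = onset_extremity or {}
    n = int(round(duration))
    assess_s = assessment_minutes * 60.0
    if duration < assess_s:
        raise SimulationError("duration shorter than the assessment period")
    if stable_assessment and any(v < 0 for v in onsets.values()):
        raise SimulationError(
            "onset inside the assessment period with stable_assessment set"
        )
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    t = np.arange(n, dtype=float)
    t_min = t / 60.0
    # trend term: linear during assessment, exponentially relaxing after
    rel = np.where(
        t <= assess_s,
        t_min,
        assessment_minutes
        + TREND_DECAY_MIN
        * (1.0 - np.exp(-(t_min - assessment_minutes) / TREND_DECAY_MIN)),
    )

    channels: dict[str, np.ndarray] = {}
    for ch in ("hr", "rr", "spo2", "map"):
        x = baselines[ch] + slopes.get(ch, 0.0) * rel
        sd = noise.get(ch, 0.0)
        if sd > 0:
            x = x + rng.normal(0.0, sd, n)
        channels[ch] = x

    for outcome, onset_min in onsets.items():
        ch, _sign = OUTCOME_CHANNEL[outcome]
        plateau, clip_at, sign = ONSET_PLATEAU[outcome]
        plateau = plateau + sign * abs(onset_extremity.get(outcome, 0.0))
        onset_i = int(round(assess_s + onset_min * 60.0))
        if onset_i >= n:
            continue
        ramp_i = min(n, onset_i + 60)
        pre = channels[ch][max(onset_i - 1, 0)]
        ramp = np.linspace(pre, plateau, ramp_i - onset_i, endpoint=False)
        channels[ch][onset_i:ramp_i] = ramp
        sd = noise.get(ch, 0.0)
        tail = plateau + (rng.normal(0.0, sd, n - ramp_i) if sd > 0 else 0.0)
        channels[ch][ramp_i:] = tail
        # keep every post-onset sample strictly beyond the threshold
        seg = channels[ch][onset_i:]
        channels[ch][onset_i:] = (
            np.minimum(seg, clip_at) if sign < 0 else np.maximum(seg, clip_at)
        )

    for ch in ("hr", "rr", "spo2", "map"):
        lo, hi = PHYSIO_CLIP[ch]
        np.clip(channels[ch], lo, hi, out=channels[ch])

    rr_interval = 60000.0 / channels["hr"]
    pi_base = baselines["perfusion_index"]
    perfusion = np.full(n, pi_base)
    if noise.get("perfusion_index", 0.0) > 0:
        perfusion = perfusion + rng.normal(0.0, noise["perfusion_index"], n)
    np.clip(perfusion, *PHYSIO_CLIP["perfusion_index"], out=perfusion)

    if missing_fraction > 0:
        mask = rng.random(n) < missing_fraction
        for ch in ("hr", "rr", "spo2", "map"):
            channels[ch] = channels[ch].copy()
            channels[ch][mask] = np.nan
        rr_interval = rr_interval.copy()
        rr_interval[mask] = np.nan

    # intermittent charting: SBP/DBP drift consistently with the MAP channel
    obs_times = np.arange(0.0, n, intermittent_minutes * 60.0)
    map_at_obs = baselines["map"] + slopes.get("map", 0.0) * np.interp(
        obs_times, t, rel
    )
    if "hypotension" in onsets:
        onset_s = assess_s + onsets["hypotension"] * 60.0
        map_at_obs = np.where(
            obs_times >= onset_s, ONSET_PLATEAU["hypotension"][0], map_at_obs
        )
    pp = baselines["sbp"] - baselines["dbp"]  # pulse pressure held constant
    sbp_values = map_at_obs + 2.0 * pp / 3.0
    dbp_values = map_at_obs - pp / 3.0
    temp_values = np.full(len(obs_times), baselines["temperature"])
    if noise.get("temperature", 0.0) > 0:
        temp_values = temp_values + rng.normal(
            0.0, noise["temperature"], len(obs_times)
        )

    return VitalStream(
        hr=channels["hr"],
        rr=channels["rr"],
        spo2=channels["spo2"],
        map=channels["map"],
        rr_interval=rr_interval,
        perfusion_index=perfusion,
        sbp_times=obs_times,
        sbp_values=sbp_values,
        dbp_times=obs_times.copy(),
        dbp_values=dbp_values,
        temperature_times=obs_times.copy(),
        temperature_values=temp_values,
    )


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


class _LazyMap(Mapping):
    """Deterministic on-demand regeneration of per-visit objects.

    Streams and waveforms for thousands of visits would not fit in memory;
    each is rebuilt from its stored parameters and child seed on access.
    """

    def __init__(self, params: dict, builder) -> None:
        self._params = params
        self._builder = builder

    def __getitem__(self, key):
        return self._builder(**self._params[key])

    def __iter__(self) -> Iterator:
        return iter(self._params)

    def __len__(self) -> int:
        return len(self._params)


@dataclass
class Cohort:
    """A simulated cohort: triage table, lazy streams, hidden ground truth."""

    config: SimConfig
    triage: pd.DataFrame  # one row per visit
    vitals: Mapping  # visit_id -> VitalStream
    rr_truth: Mapping  # visit_id -> RRGroundTruth (60-s beat train)
    waveforms: Optional[Mapping]  # visit_id -> (ecg, ppg) or None
    ground_truth: pd.DataFrame  # latent risk, events, onsets, true features

    @property
    def visit_ids(self) -> list:
        return list(self.triage["visit_id"])

    def triage_record(self, visit_id: str) -> TriageRecord:
        row = self.triage.set_index("visit_id").loc[visit_id]
        return TriageRecord(
            visit_id=visit_id,
            patient_id=row["patient_id"],
            arrival_time=float(row["arrival_time"]),
            age=float(row["age"]),
            gender=str(row["gender"]),
            esi=int(row["esi"]),
            cc_category=int(row["cc_category"]),
            hr=float(row["hr"]),
            rr=float(row["rr"]),
            spo2=float(row["spo2"]),
            sbp=float(row["sbp"]),
            dbp=float(row["dbp"]),
            map=float(row["map"]),
            temperature=float(row["temperature"]),
        )


ESI_PROBS = np.array([0.008, 0.296, 0.672, 0.016, 0.008])
ESI_PROBS = ESI_PROBS / ESI_PROBS.sum()


def generate_cohort(config: SimConfig) -> Cohort:
    """Simulate a full cohort of monitored ED visits.

    Events are Bernoulli draws with the configured prevalences, correlated
    through a shared standard-normal latent risk ``z`` (per-outcome risk =
    0.7·z + residual); onset times are uniform over the follow-up period.
    All visits satisfy the stability inclusion rules during the assessment
    period unless ``violator_fraction`` > 0.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_visits

    # --- patients and arrival chronology ---------------------------------
    n_repeat = int(0.05 * n)
    patient_of = np.arange(n)
    if n_repeat > 0 and n >= 4:
        repeats = rng.choice(n, size=n_repeat, replace=False)
        partners = rng.integers(0, n, size=n_repeat)
        patient_of[repeats] = patient_of[partners]
    arrival = np.sort(rng.uniform(0.0, 24.0 * 640, n))  # ~21 months, hours

    # --- latent risk and outcomes ----------------------------------------
    z = rng.standard_normal(n)
    w = cfg.risk_share
    events = {}
    onsets = {}
    risks = {}
    for outcome in OUTCOMES:
        risk = w * z + math.sqrt(1.0 - w * w) * rng.standard_normal(n)
        risks[outcome] = risk
        p = cfg.prevalence.get(outcome, 0.0)
        if p <= 0.0:
            ev = np.zeros(n, dtype=bool)
        else:
            ev = risk > stats.norm.ppf(1.0 - p)
        events[outcome] = ev
        onset = np.full(n, np.nan)
        lo, hi = 1.0, max(2.0, cfg.follow_minutes - 5.0)
        onset[ev] = np.floor(rng.uniform(lo, hi, ev.sum()))
        onsets[outcome] = onset

    # --- triage table -----------------------------------------------------
    age = np.clip(rng.normal(58, 18, n), 18, 100).round(0)
    gender = np.where(rng.random(n) < 0.51, "F", "M")
    esi = rng.choice(np.arange(1, 6), size=n, p=ESI_PROBS)
    cc = rng.integers(1, cfg.n_cc_categories + 1, size=n)
    hr_tri = np.clip(rng.normal(82, 10, n) + 2.0 * risks["tachycardia"], 45, 108)
    rr_tri = np.clip(rng.normal(17, 2, n), 8, 30).round(0)
    spo2_tri = np.clip(rng.normal(98, 1.2, n), 92, 100).round(0)
    sbp_tri = np.clip(rng.normal(135, 16, n) - 6.0 * risks["hypotension"], 95, 210)
    dbp_tri = np.clip(sbp_tri - rng.normal(55, 10, n), 45, 120)
    temp_tri = np.clip(rng.normal(36.9, 0.4, n), 35.0, 39.5)

    n_viol = int(round(cfg.violator_fraction * n))
    is_violator = np.zeros(n, dtype=bool)
    if n_viol > 0:
        viol_idx = rng.choice(n, size=n_viol, replace=False)
        is_violator[viol_idx] = True
        hr_tri[viol_idx] = rng.uniform(112, 135, n_viol)

    map_tri = sbp_tri / 3.0 + 2.0 * dbp_tri / 3.0
    # MAP >= 65 must hold for includable visits; enforce via DBP floor
    low = (~is_violator) & (map_tri < 70.0)
    dbp_tri[low] = (70.0 - sbp_tri[low] / 3.0) * 1.5
    map_tri = sbp_tri / 3.0 + 2.0 * dbp_tri / 3.0

    # --- recoverable physiologic signal ----------------------------------
    hr_slope = cfg.slope_effect_hr * risks["tachycardia"] + rng.normal(0, 0.06, n)
    spo2_slope = -cfg.slope_effect_spo2 * risks["hypoxia"] + rng.normal(0, 0.015, n)
    map_slope = -cfg.slope_effect_map * risks["hypotension"] + rng.normal(0, 0.05, n)
    rr_slope = rng.normal(0.0, 0.03, n)
    sdrr_true = 40.0 * np.exp(-cfg.hrv_effect * z + rng.normal(0, 0.25, n))
    sdrr_true = np.clip(sdrr_true, 5.0, 150.0)
    pi_true = 1.8 * np.exp(-cfg.perfusion_effect * z + rng.normal(0, 0.30, n))
    pi_true = np.clip(pi_true, 0.05, 15.0)
    pat_true = np.clip(rng.normal(0.25, 0.025, n), 0.15, 0.34)

    assess = cfg.assessment_minutes
    margin = 4.0
    # baselines chosen so assessment-period samples respect inclusion rules
    hr0 = np.clip(
        np.minimum(
            hr_tri + rng.normal(0, 3, n),
            THRESHOLDS["tachycardia"]
            - margin * cfg.noise["hr"]
            - np.maximum(hr_slope, 0) * assess,
        ),
        45,
        None,
    )
    spo2_0 = np.clip(
        np.maximum(
            spo2_tri + rng.normal(0, 0.5, n),
            THRESHOLDS["hypoxia"]
            + margin * cfg.noise["spo2"]
            + np.abs(np.minimum(spo2_slope, 0)) * assess,
        ),
        None,
        100.0,
    )
    map0 = np.clip(
        np.maximum(
            map_tri + rng.normal(0, 3, n),
            THRESHOLDS["hypotension"]
            + margin * cfg.noise["map"]
            + np.abs(np.minimum(map_slope, 0)) * assess,
        ),
        None,
        170.0,
    )
    rr0 = np.clip(rr_tri + rng.normal(0, 1, n), 8, 32)
    hr_wave = np.clip(hr0, 40, 180)  # waveform beat rate

    # extremity of post-onset plateaus: occasionally severe, so that the
    # composite MEWS >= 4 outcome has nonzero emergent prevalence
    extremity = {
        "tachycardia": np.abs(rng.normal(0, 9, n)),
        "hypoxia": np.abs(rng.normal(0, 4, n)),
        "hypotension": np.abs(rng.normal(0, 8, n)),
    }
    first_window_artifact = rng.random(n) < cfg.artifact_rate

    duration = (cfg.assessment_minutes + cfg.follow_minutes) * 60.0
    visit_seeds = rng.integers(0, 2**31 - 1, size=3 * n).reshape(3, n)

    visit_ids = [f"v{i:06d}" for i in range(n)]
    triage = pd.DataFrame(
        {
            "visit_id": visit_ids,
            "patient_id": [f"p{patient_of[i]:06d}" for i in range(n)],
            "arrival_time": arrival,
            "age": age,
            "gender": gender,
            "esi": esi,
            "cc_category": cc,
            "hr": hr_tri,
            "rr": rr_tri,
            "spo2": spo2_tri,
            "sbp": sbp_tri,
            "dbp": dbp_tri,
            "map": map_tri,
            "temperature": temp_tri,
        }
    )

    vit_params = {}
    rr_params = {}
    wf_params = {}
    # 90 s of beats: enough for one QC window plus a >60-s RR tachogram
    wave_duration = 90.0 if cfg.waveforms != "assessment" else assess * 60.0
    for i, vid in enumerate(visit_ids):
        vit_params[vid] = dict(
            baselines={
                "hr": float(hr0[i]), "rr": float(rr0[i]),
                "spo2": float(spo2_0[i]), "map": float(map0[i]),
                "perfusion_index": float(pi_true[i]),
                "sbp": float(map0[i] + 2.0 * (sbp_tri[i] - dbp_tri[i]) / 3.0),
                "dbp": float(map0[i] - (sbp_tri[i] - dbp_tri[i]) / 3.0),
                "temperature": float(temp_tri[i]),
            },
            slopes={
                "hr": float(hr_slope[i]), "rr": float(rr_slope[i]),
                "spo2": float(spo2_slope[i]), "map": float(map_slope[i]),
            },
            onsets={
                k: (float(onsets[k][i]) if events[k][i] else None)
                for k in OUTCOMES
            },
            noise={**cfg.noise, "perfusion_index": 0.05, "temperature": 0.1},
            duration=duration,
            seed=int(visit_seeds[0, i]),
            assessment_minutes=float(cfg.assessment_minutes),
            intermittent_minutes=float(cfg.intermittent_minutes),
            onset_extremity={k: float(extremity[k][i]) for k in OUTCOMES},
        )
        lf = 1.0 * sdrr_true[i] / math.sqrt(1.995)
        hf = 0.7 * sdrr_true[i] / math.sqrt(1.995)
        ns = 0.5 * sdrr_true[i] / math.sqrt(1.995)
        rr_params[vid] = dict(
            mean_hr=float(hr_wave[i]),
            lf_amplitude=float(lf),
            hf_amplitude=float(hf),
            noise_sd=float(ns),
            duration=wave_duration,
            seed=int(visit_seeds[1, i]),
        )
        if cfg.waveforms != "none":
            art = None
            if first_window_artifact[i]:
                art = ArtifactSpec(
                    spikes=[(10.0, 5.0)],
                    flatlines=[(20.0, 20.0, "ppg")],
                )
            wf_params[vid] = dict(
                rr_key=vid,
                pat=float(pat_true[i]),
                perfusion_index=float(pi_true[i]),
                artifact_spec=art,
                seed=int(visit_seeds[2, i]),
            )

    rr_map = _LazyMap(rr_params, generate_rr_series)

    def _build_wave(rr_key, **kw):
        return synthesize_waveform_pair(rr_map[rr_key], **kw)

    waveforms = _LazyMap(wf_params, _build_wave) if cfg.waveforms != "none" else None

    gt = pd.DataFrame(
        {
            "visit_id": visit_ids,
            "z": z,
            "sdrr_true": sdrr_true,
            "perfusion_true": pi_true,
            "pat_true": pat_true,
            "hr_slope_true": hr_slope,
            "rr_slope_true": rr_slope,
            "spo2_slope_true": spo2_slope,
            "map_slope_true": map_slope,
            "is_violator": is_violator,
            "first_window_artifact": first_window_artifact,
        }
    )
    for k in OUTCOMES:
        gt[f"event_{k}"] = events[k]
        gt[f"onset_{k}"] = onsets[k]

    return Cohort(
        config=cfg,
        triage=triage,
        vitals=_LazyMap(vit_params, generate_vitals_stream),
        rr_truth=rr_map,
        waveforms=waveforms,
        ground_truth=gt,
    )
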