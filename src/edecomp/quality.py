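"""Waveform preprocessing and signal-quality gating.

ECG quality requires a detectable heart rate between 25 and 300 bpm and no
amplitude beyond 4 mV; PPG quality requires positive skewness, consistent
systolic-wave morphology (template correlation) and absence of stationary
(flat) segments.  The first 60-second window of the assessment period in
which both waveforms pass is selected, the ECG is bandpassed 3-45 Hz and
decimated x4 from 500 Hz to the 125 Hz PPG rate, and the PPG is filtered
with a 4th-order Butterworth bandpass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps
from scipy import stats

from .types import WaveformSegment

__all__ = [
    "QCThresholds",
    "QCReport",
    "SelectedWindow",
    "detect_r_peaks",
    "assess_ecg_quality",
    "assess_ppg_quality",
    "preprocess_and_select_window",
]


@dataclass
class QCThresholds:
    """Quality gates and filter settings.

    The PPG thresholds (skewness > 0, template correlation >= 0.8,
    stationary fraction <= 5 %) are package defaults; the ECG gates
    (25-300 bpm, 4 mV) and filter bands are standard monitor practice.
    """

    hr_min: float = 25.0  # bpm
    hr_max: float = 300.0  # bpm
    ecg_amp_max: float = 4.0  # mV
    ecg_band: tuple = (3.0, 45.0)  # Hz
    ppg_filter_order: int = 4
    ppg_band: tuple = (0.5, 8.0)  # Hz
    ppg_skewness_min: float = 0.0
    ppg_systolic_match_min: float = 0.8
    ppg_stationary_frac_max: float = 0.05
    window_s: float = 60.0
    ecg_fs_raw: float = 500.0
    target_fs: float = 125.0

    def __post_init__(self) -> None:
        if not self.hr_min < self.hr_max:
            raise ValueError("hr_min must be below hr_max")
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if self.ecg_fs_raw % self.target_fs:
            raise ValueError("target_fs must divide ecg_fs_raw")


@dataclass
class QCReport:
    passed: bool
    reasons: list = field(default_factory=list)
    detected_hr: Optional[float] = None  # bpm

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must mirror an empty reason list")


@dataclass
class SelectedWindow:
    """Output of joint window selection: filtered 125-Hz pair + start time."""

    ecg: WaveformSegment
    ppg: WaveformSegment
    start_s: float
    ecg_report: QCReport
    ppg_report: QCReport


# ---------------------------------------------------------------------------
# R-peak detection (Hamilton-style)
# ---------------------------------------------------------------------------

REFRACTORY_S = 0.200  # minimum spacing between accepted beats
_TH_FRACTION = 0.3125  # detection threshold between noise and signal levels


def detect_r_peaks(ecg: WaveformSegment) -> tuple[np.ndarray, np.ndarray]:
    """Detect R-peaks; returns (sample indices, RR intervals in ms).

    The detector follows Hamilton's recipe: bandpass around the QRS energy
    (8-20 Hz), differentiate, rectify, integrate with an 80-ms moving
    average, then accept local maxima against an adaptive threshold placed
    between running noise- and signal-peak averages, with a 200-ms
    refractory period.  Accepted detections are refined to the local
    extremum of the raw signal.
    """
    if ecg.modality != "ecg":
        raise ValueError(f"expected ECG, got {ecg.modality!r}")
    x = ecg.samples
    fs = ecg.fs
    if len(x) < 2 * fs:
        raise ValueError("need at least 2 s of ECG")
    if np.max(np.abs(x)) == 0.0:
        return np.array([], dtype=int), np.array([])

    sos = sps.butter(2, [8.0, 20.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    det = np.abs(np.diff(bp, prepend=bp[0]))
    win = max(1, int(0.080 * fs))
    integ = np.convolve(det, np.ones(win) / win, mode="same")

    dist = max(1, int(REFRACTORY_S * fs))
    cand, _ = sps.find_peaks(integ, distance=dist)
    if len(cand) == 0:
        return np.array([], dtype=int), np.array([])

    # adaptive threshold sweep over candidates
    spk = float(np.percentile(integ[cand], 90))
    npk = float(np.percentile(integ, 50))
    accepted: list[int] = []
    for c in cand:
        h = integ[c]
        th = npk + _TH_FRACTION * (spk - npk)
        if h > th:
            if accepted and (c - accepted[-1]) < dist:
                if h > integ[accepted[-1]]:
                    accepted[-1] = c
            else:
                accepted.append(c)
            spk = 0.125 * h + 0.875 * spk
        else:
            npk = 0.125 * h + 0.875 * npk

    # refine to the raw-signal extremum near each detection
    half = max(1, int(0.06 * fs))
    sign = 1.0 if abs(np.max(x)) >= abs(np.min(x)) else -1.0
    refined = []
    for c in accepted:
        i0, i1 = max(0, c - half), min(len(x), c + half + 1)
        refined.append(i0 + int(np.argmax(sign * x[i0:i1])))
    peaks = np.unique(np.asarray(refined, dtype=int))
    if len(peaks) > 1:
        keep = np.concatenate([[True], np.diff(peaks) >= dist])
        peaks = peaks[keep]
    rr_ms = np.diff(peaks) / fs * 1000.0
    return peaks, rr_ms


def detected_heart_rate(rr_ms: np.ndarray) -> Optional[float]:
    """HR in bpm implied by detected RR intervals; None if < 1 interval."""
    if len(rr_ms) == 0:
        return None
    return 60000.0 / float(np.mean(rr_ms))


# ---------------------------------------------------------------------------
# Quality gates
# ---------------------------------------------------------------------------


def assess_ecg_quality(
    ecg: WaveformSegment, th: Optional[QCThresholds] = None
) -> QCReport:
    """Gate an ECG segment on detectable HR (25-300 bpm) and 4 mV amplitude."""
    th = th or QCThresholds()
    reasons = []
    peaks, rr_ms = detect_r_peaks(ecg)
    hr = detected_heart_rate(rr_ms)
    if hr is None:
        reasons.append("NO_PEAKS")
    elif not th.hr_min <= hr <= th.hr_max:
        reasons.append("HR_RANGE")
    if np.any(np.abs(ecg.samples) > th.ecg_amp_max):
        reasons.append("AMPLITUDE")
    return QCReport(passed=not reasons, reasons=reasons, detected_hr=hr)


def _stationary_fraction(x: np.ndarray, fs: float, window_s: float = 2.0) -> float:
    """Fraction of the segment whose running 2-s std collapses toward zero."""
    w = max(2, int(window_s * fs))
    c1 = np.convolve(x, np.ones(w) / w, mode="same")
    c2 = np.convolve(x * x, np.ones(w) / w, mode="same")
    var = np.maximum(c2 - c1 * c1, 0.0)
    overall = float(np.std(x))
    if overall == 0.0:
        return 1.0
    return float(np.mean(np.sqrt(var) < 0.05 * overall))


def _systolic_match(x: np.ndarray, fs: float) -> float:
    """Mean correlation of each detected pulse with the segment's template."""
    amp = np.max(x) - np.min(x)
    if amp == 0.0:
        return 0.0
    dist = max(1, int(0.3 * fs))
    peaks, _ = sps.find_peaks(x, distance=dist, prominence=0.3 * amp)
    if len(peaks) < 3:
        return 0.0
    gap = np.median(np.diff(peaks))
    half = int(0.4 * gap)
    if half < 2:
        return 0.0
    beats = [
        x[p - half : p + half]
        for p in peaks
        if p - half >= 0 and p + half <= len(x)
    ]
    if len(beats) < 3:
        return 0.0
    beats_arr = np.asarray(beats)
    template = beats_arr.mean(axis=0)
    t_c = template - template.mean()
    t_norm = np.linalg.norm(t_c)
    if t_norm == 0.0:
        return 0.0
    corrs = []
    for b in beats_arr:
        b_c = b - b.mean()
        d = np.linalg.norm(b_c) * t_norm
        corrs.append(float(b_c @ t_c / d) if d > 0 else 0.0)
    return float(np.mean(corrs))


def assess_ppg_quality(
    ppg: WaveformSegment, th: Optional[QCThresholds] = None
) -> QCReport:
    """Gate a PPG segment on skewness, systolic-wave matching, stationarity."""
    th = th or QCThresholds()
    x = ppg.samples
    reasons = []
    if stats.skew(x) <= th.ppg_skewness_min:
        reasons.append("SKEWNESS")
    if _systolic_match(x, ppg.fs) < th.ppg_systolic_match_min:
        reasons.append("SYSTOLIC_MATCH")
    if _stationary_fraction(x, ppg.fs) > th.ppg_stationary_frac_max:
        reasons.append("STATIONARY")
    return QCReport(passed=not reasons, reasons=reasons)


# ---------------------------------------------------------------------------
# Filtering, decimation and joint window selection
# ---------------------------------------------------------------------------


def filter_ecg(ecg: WaveformSegment, th: Optional[QCThresholds] = None) -> WaveformSegment:
    """3-45 Hz bandpass then x4 decimation to 125 Hz.

    The 45-Hz upper edge sits below the 62.5-Hz post-decimation Nyquist, so
    the bandpass doubles as the anti-alias filter.  Output length is
    ceil(input / 4).
    """
    th = th or QCThresholds()
    q = int(th.ecg_fs_raw // th.target_fs)
    sos = sps.butter(3, th.ecg_band, btype="bandpass", fs=ecg.fs, output="sos")
    y = sps.sosfiltfilt(sos, ecg.samples)
    return WaveformSegment("ecg", ecg.fs / q, y[::q], ecg.start_time)


def filter_ppg(ppg: WaveformSegment, th: Optional[QCThresholds] = None) -> WaveformSegment:
    """4th-order Butterworth bandpass (default 0.5-8 Hz) at native rate."""
    th = th or QCThresholds()
    sos = sps.butter(
        th.ppg_filter_order, th.ppg_band, btype="bandpass", fs=ppg.fs,
        output="sos",
    )
    return WaveformSegment("ppg", ppg.fs, sps.sosfiltfilt(sos, ppg.samples),
                           ppg.start_time)


def preprocess_and_select_window(
    ecg: WaveformSegment,
    ppg: WaveformSegment,
    th: Optional[QCThresholds] = None,
    assessment_minutes: float = 15.0,
) -> Optional[SelectedWindow]:
    """Scan non-overlapping 60-s windows; return the first jointly clean one.

    Windows start at t = 0, 60, 120, ... seconds within the assessment
    period.  Returns None (exclusion) when no window passes both gates.
    """
    th = th or QCThresholds()
    w = th.window_s
    horizon = min(assessment_minutes * 60.0, ecg.duration_s, ppg.duration_s)
    if horizon < w:
        raise ValueError("streams shorter than one QC window")
    start = 0.0
    while start + w <= horizon + 1e-9:
        e_win = ecg.slice(start, start + w)
        p_win = ppg.slice(start, start + w)
        e_rep = assess_ecg_quality(e_win, th)
        p_rep = assess_ppg_quality(p_win, th)
        if e_rep.passed and p_rep.passed:
            return SelectedWindow(
                ecg=filter_ecg(e_win, th),
                ppg=filter_ppg(p_win, th),
                start_s=start,
                ecg_report=e_rep,
                ppg_report=p_rep,
            )
        start += w
    return None
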