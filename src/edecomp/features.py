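"""Engineered physiologic features: HRV (time & frequency domain) and PAT.

Time-domain HRV statistics are computed from beat-to-beat RR intervals;
frequency-domain statistics from a Welch power spectral density, by default
of the 60-s ECG signal itself, with an alternative mode operating on the
evenly-resampled RR tachogram (the conventional HRV substrate).  Pulse
arrival time is the mean delay from each ECG R-peak to the next PPG pulse
peak, with pairs further apart than the local RR interval discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Optional

import numpy as np
from scipy import interpolate
from scipy import signal as sps

__all__ = [
    "HRVFeatures",
    "PATResult",
    "time_domain_hrv",
    "frequency_domain_hrv",
    "rr_tachogram",
    "pulse_arrival_time",
]

#: HRV Task Force histogram bin width for the triangular index / TINN
HIST_BIN_MS = 1000.0 / 128.0  # 7.8125 ms

LF_BAND = (0.04, 0.15)  # Hz
HF_BAND = (0.15, 0.40)  # Hz


@dataclass
class HRVFeatures:
    """The full HRV feature vector; unset entries are None (missing)."""

    sdrr: Optional[float] = None  # ms
    rmssd: Optional[float] = None  # ms
    prr50: Optional[float] = None  # %
    tri_index: Optional[float] = None
    tinn: Optional[float] = None  # ms
    lf_peak: Optional[float] = None  # Hz
    hf_peak: Optional[float] = None  # Hz
    lf_power: Optional[float] = None
    hf_power: Optional[float] = None
    lf_rel: Optional[float] = None
    hf_rel: Optional[float] = None
    lf_hf_ratio: Optional[float] = None

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def merge(self, other: "HRVFeatures") -> "HRVFeatures":
        out = HRVFeatures(**self.as_dict())
        for f in fields(other):
            v = getattr(other, f.name)
            if v is not None:
                setattr(out, f.name, v)
        return out


HRV_FIELDS = tuple(f.name for f in fields(HRVFeatures))


@dataclass
class PATResult:
    pat_mean: Optional[float]  # s
    n_pairs: int
    n_discarded: int


# ---------------------------------------------------------------------------
# Time domain
# ---------------------------------------------------------------------------


def time_domain_hrv(rr_intervals: np.ndarray, tinn_method: str = "width") -> HRVFeatures:
    """Time-domain HRV from RR intervals (ms).

    * SDRR: sample standard deviation (n-1 denominator).
    * RMSSD: root mean square of successive differences.
    * pRR50: percentage of successive differences strictly exceeding 50 ms.
    * Triangular index: N / max bin count of the RR histogram (1/128-s bins
      aligned to multiples of the bin width).
    * TINN: by default the plain width of the occupied histogram support;
      ``tinn_method="interpolation"`` instead fits the classical triangle
      (least-squares over candidate base points) and reports its base width.

    Fewer than 3 intervals yield an all-missing result.
    """
    rr = np.asarray(rr_intervals, dtype=float)
    rr = rr[np.isfinite(rr)]
    if len(rr) < 3:
        return HRVFeatures()
    diffs = np.diff(rr)
    sdrr = float(np.std(rr, ddof=1))
    rmssd = float(math.sqrt(np.mean(diffs**2)))
    prr50 = float(100.0 * np.mean(np.abs(diffs) > 50.0))

    counts, edges = _rr_histogram(rr)
    tri_index = float(len(rr) / counts.max())
    occupied = np.nonzero(counts)[0]
    if tinn_method == "width":
        tinn = float(edges[occupied[-1] + 1] - edges[occupied[0]])
    elif tinn_method == "interpolation":
        tinn = _tinn_triangular(counts, edges)
    else:
        raise ValueError(f"unknown tinn_method {tinn_method!r}")
    return HRVFeatures(
        sdrr=sdrr, rmssd=rmssd, prr50=prr50, tri_index=tri_index, tinn=tinn
    )


def _rr_histogram(rr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = math.floor(rr.min() / HIST_BIN_MS) * HIST_BIN_MS
    hi = math.ceil(rr.max() / HIST_BIN_MS) * HIST_BIN_MS
    if hi <= lo:
        hi = lo + HIST_BIN_MS
    edges = np.arange(lo, hi + HIST_BIN_MS / 2, HIST_BIN_MS)
    counts, _ = np.histogram(rr, bins=edges)
    return counts, edges


def _tinn_triangular(counts: np.ndarray, edges: np.ndarray) -> float:
    """Classical TINN: base of the best-fitting triangle over the histogram."""
    centers = (edges[:-1] + edges[1:]) / 2.0
    k = int(np.argmax(counts))
    peak_x, peak_y = centers[k], float(counts[k])
    best = (np.inf, centers[-1] - centers[0])
    for i in range(0, k):
        for j in range(k + 1, len(centers)):
            tri = np.zeros_like(centers)
            left = (centers >= centers[i]) & (centers <= peak_x)
            right = (centers > peak_x) & (centers <= centers[j])
            if peak_x > centers[i]:
                tri[left] = peak_y * (centers[left] - centers[i]) / (peak_x - centers[i])
            if centers[j] > peak_x:
                tri[right] = peak_y * (centers[j] - centers[right]) / (centers[j] - peak_x)
            err = float(np.sum((counts - tri) ** 2))
            if err < best[0]:
                best = (err, centers[j] - centers[i])
    return float(best[1])


# ---------------------------------------------------------------------------
# Frequency domain
# ---------------------------------------------------------------------------


def rr_tachogram(
    beat_times: np.ndarray, rr_intervals: np.ndarray, fs: float = 4.0
) -> tuple[np.ndarray, float]:
    """Evenly resample the RR tachogram (cubic interpolation) at ``fs`` Hz."""
    t = np.asarray(beat_times, dtype=float)[1:]
    rr = np.asarray(rr_intervals, dtype=float)
    if len(t) < 4:
        raise ValueError("need at least 4 beats for cubic resampling")
    grid = np.arange(t[0], t[-1], 1.0 / fs)
    f = interpolate.CubicSpline(t, rr)
    return f(grid), fs


def frequency_domain_hrv(x: np.ndarray, fs: float) -> HRVFeatures:
    """Frequency-domain HRV measures from a signal's Welch PSD.

    Per band (LF 0.04-0.15 Hz, HF 0.15-0.4 Hz): peak frequency, absolute
    power, and power relative to the total over 0.04-0.4 Hz; plus the LF/HF
    power ratio (missing when HF power is zero).  ``x`` may be the 60-s ECG
    signal itself or an evenly-resampled RR tachogram.
    """
    x = np.asarray(x, dtype=float)
    if len(x) / fs < 60.0 - 1e-9:
        raise ValueError("need at least 60 s of signal")
    freqs, psd = sps.welch(
        x, fs=fs, window="hann", nperseg=len(x), detrend="constant"
    )
    df = freqs[1] - freqs[0]
    lf_mask = (freqs >= LF_BAND[0]) & (freqs < LF_BAND[1])
    hf_mask = (freqs >= HF_BAND[0]) & (freqs <= HF_BAND[1])
    tot_mask = (freqs >= LF_BAND[0]) & (freqs <= HF_BAND[1])
    lf_power = float(np.sum(psd[lf_mask]) * df)
    hf_power = float(np.sum(psd[hf_mask]) * df)
    total = float(np.sum(psd[tot_mask]) * df)
    lf_peak = float(freqs[lf_mask][np.argmax(psd[lf_mask])]) if lf_mask.any() else None
    hf_peak = float(freqs[hf_mask][np.argmax(psd[hf_mask])]) if hf_mask.any() else None
    return HRVFeatures(
        lf_peak=lf_peak,
        hf_peak=hf_peak,
        lf_power=lf_power,
        hf_power=hf_power,
        lf_rel=lf_power / total if total > 0 else None,
        hf_rel=hf_power / total if total > 0 else None,
        lf_hf_ratio=lf_power / hf_power if hf_power > 0 else None,
    )


# ---------------------------------------------------------------------------
# Pulse arrival time
# ---------------------------------------------------------------------------


def pulse_arrival_time(
    ecg_peaks: np.ndarray,
    ppg_peaks: np.ndarray,
    rr_intervals: np.ndarray,
) -> PATResult:
    """Mean R-peak -> next PPG-peak delay over valid pairs.

    For each ECG peak the candidate PPG peak is the first one strictly
    after it; the pair is kept iff the delay does not exceed the RR
    interval beginning at that ECG peak (the last peak reuses the final
    interval).  Peak times in seconds, RR intervals in ms.
    """
    ecg_peaks = np.asarray(ecg_peaks, dtype=float)
    ppg_peaks = np.asarray(ppg_peaks, dtype=float)
    rr_s = np.asarray(rr_intervals, dtype=float) / 1000.0
    if np.any(np.diff(ecg_peaks) < 0) or np.any(np.diff(ppg_peaks) < 0):
        raise ValueError("peak lists must be sorted ascending")
    delays = []
    n_discarded = 0
    for i, te in enumerate(ecg_peaks):
        j = np.searchsorted(ppg_peaks, te, side="right")
        if j >= len(ppg_peaks):
            n_discarded += 1
            continue
        delay = ppg_peaks[j] - te
        rr_here = rr_s[i] if i < len(rr_s) else (rr_s[-1] if len(rr_s) else np.inf)
        if delay <= rr_here:
            delays.append(delay)
        else:
            n_discarded += 1
    if not delays:
        return PATResult(pat_mean=None, n_pairs=0, n_discarded=n_discarded)
    return PATResult(
        pat_mean=float(np.mean(delays)),
        n_pairs=len(delays),
        n_discarded=n_discarded,
    )


def ppg_pulse_peaks(
    samples: np.ndarray, fs: float, refine_on: Optional[np.ndarray] = None
) -> np.ndarray:
    """Systolic peak times (s) of a PPG segment via prominence-gated maxima.

    Detection runs on ``samples`` (typically the bandpassed signal, robust
    to baseline wander); when ``refine_on`` is given (the raw signal) each
    peak is snapped to the raw local maximum within +/-40 ms, since smoothing
    an asymmetric pulse shifts its apex.
    """
    amp = np.max(samples) - np.min(samples)
    if amp == 0:
        return np.array([])
    peaks, _ = sps.find_peaks(
        samples, distance=max(1, int(0.3 * fs)), prominence=0.3 * amp
    )
    if refine_on is not None and len(peaks):
        half = max(1, int(0.04 * fs))
        refined = []
        for p in peaks:
            i0, i1 = max(0, p - half), min(len(refine_on), p + half + 1)
            refined.append(i0 + int(np.argmax(refine_on[i0:i1])))
        peaks = np.unique(refined)
    return peaks / fs
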