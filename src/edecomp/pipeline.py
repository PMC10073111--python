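"""End-to-end assembly: cohort -> per-visit feature and label tables.

Streams are processed one visit at a time (they are regenerated lazily),
so cohorts of thousands of visits fit comfortably in memory.  Two waveform
paths exist:

* measured: when the cohort carries rendered ECG/PPG pairs, the joint
  60-s window is QC-selected, R-peaks are detected, and HRV/PAT are
  measured from the signals exactly as at deployment;
* beat-train: when waveforms were not rendered, time- and
  frequency-domain HRV are computed from the simulator's ground-truth
  beat train (the same RR substrate the waveforms would encode) and PAT
  is left missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import quality
from .cohort import (
    InclusionRules,
    apply_inclusion,
    compute_mews_series,
    label_outcomes,
    minute_trends,
    encode_triage,
    TRIAGE_FEATURE_NAMES,
)
from .features import (
    HRV_FIELDS,
    frequency_domain_hrv,
    ppg_pulse_peaks,
    pulse_arrival_time,
    rr_tachogram,
    time_domain_hrv,
)
from .synth import Cohort
from .types import Visit

__all__ = ["VisitTables", "extract_tables", "waveform_features_from_pair"]

LABEL_WINDOWS = (60, 90, 120)
LABEL_OUTCOMES = ("tachycardia", "hypoxia", "hypotension", "mews4")


@dataclass
class VisitTables:
    """Per-visit features, labels and bookkeeping for a cohort."""

    features: pd.DataFrame  # indexed by visit_id
    labels: pd.DataFrame  # columns "<outcome>_<window>"
    max_mews: pd.DataFrame  # columns "max_mews_<window>"
    excluded: pd.DataFrame  # visit_id, reason


def waveform_features_from_pair(
    ecg, ppg, th: Optional[quality.QCThresholds] = None,
    assessment_minutes: Optional[float] = None,
    freq_source: str = "ecg",
) -> Optional[dict]:
    """QC-select a joint window and measure HRV + PAT from it.

    Returns None when no jointly acceptable 60-s window exists.
    ``freq_source`` chooses the frequency-domain substrate: the filtered
    ECG signal itself ("ecg") or the evenly-resampled RR tachogram
    ("tachogram").
    """
    th = th or quality.QCThresholds()
    if assessment_minutes is None:
        assessment_minutes = ecg.duration_s / 60.0
    sel = quality.preprocess_and_select_window(ecg, ppg, th, assessment_minutes)
    if sel is None:
        return None
    peaks, rr_ms = quality.detect_r_peaks(sel.ecg)
    hrv = time_domain_hrv(rr_ms)
    if freq_source == "ecg":
        hrv = hrv.merge(frequency_domain_hrv(sel.ecg.samples, sel.ecg.fs))
    elif len(peaks) >= 5:
        beat_times = peaks / sel.ecg.fs
        tach, tfs = rr_tachogram(beat_times, rr_ms, fs=4.0)
        if len(tach) / tfs >= 60.0:
            hrv = hrv.merge(frequency_domain_hrv(tach, tfs))
    ecg_peak_times = peaks / sel.ecg.fs
    raw_win = ppg.slice(sel.start_s, sel.start_s + th.window_s)
    ppg_peak_times = ppg_pulse_peaks(
        sel.ppg.samples, sel.ppg.fs, refine_on=raw_win.samples
    )
    pat = pulse_arrival_time(ecg_peak_times, ppg_peak_times, rr_ms)
    out = hrv.as_dict()
    out["pat_mean"] = pat.pat_mean
    out["pat_n_pairs"] = pat.n_pairs
    out["window_start_s"] = sel.start_s
    return out


def extract_tables(
    cohort: Cohort,
    rules: Optional[InclusionRules] = None,
    th: Optional[quality.QCThresholds] = None,
    freq_hrv_source: str = "ecg",
) -> VisitTables:
    """Run inclusion, trends, MEWS, labels and waveform features per visit.

    ``freq_hrv_source`` selects the frequency-domain HRV substrate on the
    measured-waveform path ("ecg" = the filtered ECG signal's PSD,
    "tachogram" = the resampled RR series); the beat-train path always
    uses the tachogram, the only substrate it has.
    """
    cfg = cohort.config
    rules = rules or InclusionRules(assessment_minutes=cfg.assessment_minutes)
    a_min = cfg.assessment_minutes
    rows, label_rows, mews_rows, excluded = [], [], [], []
    has_waves = cohort.waveforms is not None
    triage_idx = cohort.triage.set_index("visit_id")

    for vid in cohort.visit_ids:
        tri = cohort.triage_record(vid)
        stream = cohort.vitals[vid]
        ecg = ppg = None
        if has_waves:
            ecg, ppg = cohort.waveforms[vid]
        visit = Visit(triage=tri, vitals=stream, ecg=ecg, ppg=ppg)
        if not has_waves:
            # inclusion without the waveform-presence requirement
            loose = InclusionRules(
                hr_max_ok=rules.hr_max_ok, spo2_min_ok=rules.spo2_min_ok,
                map_min_ok=rules.map_min_ok,
                assessment_minutes=rules.assessment_minutes,
                require_each_vital_and_waveform=False,
            )
            inc = apply_inclusion(visit, loose)
        else:
            inc = apply_inclusion(visit, rules)
        if not inc.included:
            excluded.append({"visit_id": vid, "reason": inc.reason})
            continue

        feat = dict(zip(TRIAGE_FEATURE_NAMES, encode_triage(tri)))
        trends = minute_trends(stream, a_min)
        for ch in ("hr", "rr", "spo2", "map"):
            feat[f"{ch}_first"] = trends[ch]["first"]
            feat[f"{ch}_slope"] = trends[ch]["slope"]
        feat["sbp_first"] = (
            float(stream.sbp_values[0]) if len(stream.sbp_values) else np.nan
        )
        feat["dbp_first"] = (
            float(stream.dbp_values[0]) if len(stream.dbp_values) else np.nan
        )
        feat["perfusion_index"] = float(
            np.nanmean(stream.perfusion_index[: a_min * 60])
        )

        if has_waves:
            wf = waveform_features_from_pair(
                ecg, ppg, th, assessment_minutes=min(a_min, ecg.duration_s / 60.0),
                freq_source=freq_hrv_source,
            )
            if wf is None:
                for k in HRV_FIELDS:
                    feat[k] = np.nan
                feat["pat_mean"] = np.nan
                feat["pat_n_pairs"] = 0
            else:
                for k in HRV_FIELDS:
                    feat[k] = wf[k]
                feat["pat_mean"] = wf["pat_mean"]
                feat["pat_n_pairs"] = wf["pat_n_pairs"]
        else:
            rr = cohort.rr_truth[vid]
            hrv = time_domain_hrv(rr.rr_intervals)
            if len(rr.beat_times) >= 5:
                tach, tfs = rr_tachogram(rr.beat_times, rr.rr_intervals, fs=4.0)
                if len(tach) / tfs >= 60.0:
                    hrv = hrv.merge(frequency_domain_hrv(tach, tfs))
            for k in HRV_FIELDS:
                feat[k] = hrv.as_dict()[k]
            feat["pat_mean"] = np.nan
            feat["pat_n_pairs"] = 0

        feat["visit_id"] = vid
        rows.append(feat)

        mews = compute_mews_series(stream)
        labels = label_outcomes(stream, mews, a_min, LABEL_WINDOWS)
        lrow = {"visit_id": vid}
        for outcome in LABEL_OUTCOMES:
            for w in LABEL_WINDOWS:
                lrow[f"{outcome}_{w}"] = labels[(outcome, w)]
        label_rows.append(lrow)
        mrow = {"visit_id": vid}
        for w in LABEL_WINDOWS:
            seg = mews.total[a_min : a_min + w]
            seg = seg[np.isfinite(seg)]
            mrow[f"max_mews_{w}"] = float(seg.max()) if len(seg) else np.nan
        mews_rows.append(mrow)

    features = pd.DataFrame(rows).set_index("visit_id")
    features = features.apply(
        lambda col: pd.to_numeric(col, errors="coerce"), axis=0
    )
    labels = pd.DataFrame(label_rows).set_index("visit_id")
    max_mews = pd.DataFrame(mews_rows).set_index("visit_id")
    excluded_df = pd.DataFrame(excluded, columns=["visit_id", "reason"])
    # keep the triage chronology columns available for splitting
    features = features.join(
        triage_idx[["patient_id", "arrival_time"]], how="left"
    )
    return VisitTables(
        features=features, labels=labels, max_mews=max_mews,
        excluded=excluded_df,
    )
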