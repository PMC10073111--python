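"""Cohort construction: inclusion, trends, MEWS, labels, splits, encoding.

The study population is visits with grossly normal vitals (HR <= 110,
SpO2 >= 90, MAP >= 65) at triage and throughout the first 15 minutes of
monitoring.  Outcomes are strict threshold crossings of one-minute channel
means in a 60/90/120-minute window after the assessment period, plus a
composite outcome of the minute-level Modified Early Warning Score
reaching 4 (neurologic component omitted; intermittent blood pressure and
temperature carried forward).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .types import TriageRecord, VitalStream

__all__ = [
    "InclusionRules",
    "InclusionResult",
    "MEWSSeries",
    "OutcomeLabels",
    "SplitAssignment",
    "apply_inclusion",
    "minute_means",
    "minute_trends",
    "compute_mews_series",
    "label_outcomes",
    "split_cohort",
    "encode_triage",
    "TRIAGE_FEATURE_NAMES",
    "MEWS_TABLE",
]

OUTCOMES = ("tachycardia", "hypoxia", "hypotension", "mews4")
WINDOWS = (60, 90, 120)


@dataclass
class InclusionRules:
    hr_max_ok: float = 110.0  # bpm
    spo2_min_ok: float = 90.0  # %
    map_min_ok: float = 65.0  # mmHg
    assessment_minutes: int = 15
    require_each_vital_and_waveform: bool = True


@dataclass
class InclusionResult:
    included: bool
    reason: Optional[str] = None  # which rule fired, e.g. "HR_TRIAGE"


def apply_inclusion(visit, rules: Optional[InclusionRules] = None) -> InclusionResult:
    """Stability screen at triage and over the assessment period.

    ``visit`` needs ``.triage`` (TriageRecord), ``.vitals`` (VitalStream)
    and optionally ``.ecg`` / ``.ppg`` waveform segments.  Exclusion is a
    value, not an error; the reason names the first rule violated.
    """
    rules = rules or InclusionRules()
    tri: TriageRecord = visit.triage
    if tri.hr > rules.hr_max_ok:
        return InclusionResult(False, "HR_TRIAGE")
    if tri.spo2 < rules.spo2_min_ok:
        return InclusionResult(False, "SPO2_TRIAGE")
    if tri.map < rules.map_min_ok:
        return InclusionResult(False, "MAP_TRIAGE")
    vs: VitalStream = visit.vitals
    if vs is None:
        return InclusionResult(False, "MISSING_VITAL")
    n = int(rules.assessment_minutes * 60)
    checks = (
        ("hr", lambda a: np.nanmax(a) > rules.hr_max_ok, "HR_ASSESSMENT"),
        ("spo2", lambda a: np.nanmin(a) < rules.spo2_min_ok, "SPO2_ASSESSMENT"),
        ("map", lambda a: np.nanmin(a) < rules.map_min_ok, "MAP_ASSESSMENT"),
    )
    for ch, bad, reason in checks:
        seg = getattr(vs, ch)[:n]
        if np.isfinite(seg).any() and bad(seg):
            return InclusionResult(False, reason)
    if rules.require_each_vital_and_waveform:
        for ch in ("hr", "rr", "spo2", "map"):
            if not np.isfinite(getattr(vs, ch)).any():
                return InclusionResult(False, "MISSING_VITAL")
        if len(vs.sbp_values) == 0 or len(vs.temperature_values) == 0:
            return InclusionResult(False, "MISSING_VITAL")
        ecg = getattr(visit, "ecg", None)
        ppg = getattr(visit, "ppg", None)
        for wf in (ecg, ppg):
            if wf is None or len(wf.samples) == 0:
                return InclusionResult(False, "MISSING_WAVEFORM")
    return InclusionResult(True)


# ---------------------------------------------------------------------------
# Minute means and linear trends
# ---------------------------------------------------------------------------

TREND_CHANNELS = ("hr", "rr", "spo2", "map")


def minute_means(samples: np.ndarray, n_minutes: Optional[int] = None) -> np.ndarray:
    """Means over non-overlapping [t, t+60 s) bins; NaN where a bin is empty."""
    total = len(samples) // 60 if n_minutes is None else n_minutes
    out = np.full(total, np.nan)
    for m in range(total):
        seg = samples[m * 60 : (m + 1) * 60]
        if np.isfinite(seg).any():
            out[m] = np.nanmean(seg)
    return out


def minute_trends(stream: VitalStream, assessment_minutes: int = 15) -> dict:
    """First minute mean and OLS slope (units/min) per continuous channel.

    Missing minutes are dropped from the fit; channels with fewer than two
    usable minutes report a missing slope.
    """
    out = {}
    for ch in TREND_CHANNELS:
        mm = minute_means(getattr(stream, ch)[: assessment_minutes * 60])
        ok = np.isfinite(mm)
        first = float(mm[ok][0]) if ok.any() else None
        if ok.sum() >= 2:
            idx = np.nonzero(ok)[0].astype(float)
            slope = float(np.polyfit(idx, mm[ok], 1)[0])
        else:
            slope = None
        out[ch] = {"first": first, "slope": slope}
    return out


# ---------------------------------------------------------------------------
# MEWS
# ---------------------------------------------------------------------------

#: component scoring bands: list of (lower, upper, score) with lower <= v < upper
MEWS_TABLE = {
    "sbp": [
        (-np.inf, 70.0 + 1e-9, 3),
        (70.0 + 1e-9, 80.0 + 1e-9, 2),
        (80.0 + 1e-9, 100.0 + 1e-9, 1),
        (100.0 + 1e-9, 200.0, 0),
        (200.0, np.inf, 2),
    ],
    "hr": [
        (-np.inf, 40.0, 2),
        (40.0, 51.0, 1),
        (51.0, 101.0, 0),
        (101.0, 111.0, 1),
        (111.0, 130.0, 2),
        (130.0, np.inf, 3),
    ],
    "rr": [
        (-np.inf, 9.0, 2),
        (9.0, 15.0, 0),
        (15.0, 21.0, 1),
        (21.0, 30.0, 2),
        (30.0, np.inf, 3),
    ],
    "temperature": [
        (-np.inf, 35.0, 2),
        (35.0, 38.5, 0),
        (38.5, np.inf, 2),
    ],
}


def score_component(channel: str, value: float, table: Optional[dict] = None) -> int:
    table = table or MEWS_TABLE
    for lo, hi, score in table[channel]:
        if lo <= value < hi:
            return score
    raise ValueError(f"value {value} not covered by {channel} bands")


@dataclass
class MEWSSeries:
    """Minute-level MEWS (neurologic component omitted).

    ``total[m]`` is NaN before every component has been observed at least
    once.  ``carried[ch][m]`` is True where the component used a
    carried-forward intermittent observation rather than a same-minute one.
    """

    total: np.ndarray  # float; NaN = not yet computable
    components: dict  # channel -> float array
    carried: dict  # channel -> bool array


def _carry_forward(times: np.ndarray, values: np.ndarray, n_minutes: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Last observed value per minute; NaN before the first observation."""
    out = np.full(n_minutes, np.nan)
    carried = np.zeros(n_minutes, dtype=bool)
    if len(times) == 0:
        return out, carried
    obs_min = np.asarray(times, dtype=float) / 60.0
    for m in range(n_minutes):
        k = np.searchsorted(obs_min, m + 1.0, side="left") - 1
        if k >= 0:
            out[m] = values[k]
            carried[m] = obs_min[k] < m  # observed in an earlier minute
    return out, carried


def compute_mews_series(
    stream: VitalStream, table: Optional[dict] = None
) -> MEWSSeries:
    """Score MEWS at each minute from minute means (HR, RR) and
    carried-forward intermittent observations (SBP, temperature)."""
    table = table or MEWS_TABLE
    n_min = stream.duration_s // 60
    hr_mm = minute_means(stream.hr, n_min)
    rr_mm = minute_means(stream.rr, n_min)
    sbp_cf, sbp_car = _carry_forward(stream.sbp_times, stream.sbp_values, n_min)
    tmp_cf, tmp_car = _carry_forward(
        stream.temperature_times, stream.temperature_values, n_min
    )
    if not (np.isfinite(hr_mm).any() and np.isfinite(rr_mm).any()
            and np.isfinite(sbp_cf).any() and np.isfinite(tmp_cf).any()):
        raise ValueError("a MEWS component channel was never observed")

    comps = {}
    values = {"hr": hr_mm, "rr": rr_mm, "sbp": sbp_cf, "temperature": tmp_cf}
    for ch, arr in values.items():
        scored = np.full(n_min, np.nan)
        ok = np.isfinite(arr)
        scored[ok] = [score_component(ch, v, table) for v in arr[ok]]
        comps[ch] = scored
    total = comps["hr"] + comps["rr"] + comps["sbp"] + comps["temperature"]
    carried = {
        "hr": np.zeros(n_min, dtype=bool),
        "rr": np.zeros(n_min, dtype=bool),
        "sbp": sbp_car,
        "temperature": tmp_car,
    }
    return MEWSSeries(total=total, components=comps, carried=carried)


# ---------------------------------------------------------------------------
# Outcome labels
# ---------------------------------------------------------------------------

LABEL_RULES = {
    "tachycardia": ("hr", lambda mm: mm > 110.0),
    "hypoxia": ("spo2", lambda mm: mm < 90.0),
    "hypotension": ("map", lambda mm: mm < 65.0),
}


@dataclass
class OutcomeLabels:
    """Boolean label per (outcome, window); None where follow-up is short.

    ``onset_minute[outcome]`` is the first crossing minute after the
    assessment period (1-based), or None.
    """

    labels: dict  # (outcome, window) -> bool | None
    onset_minute: dict  # outcome -> int | None

    def __getitem__(self, key):
        return self.labels[key]


def label_outcomes(
    stream: VitalStream,
    mews: Optional[MEWSSeries] = None,
    assessment_minutes: int = 15,
    windows: tuple = WINDOWS,
    mews_threshold: int = 4,
) -> OutcomeLabels:
    """Label strict threshold crossings of minute means per window.

    A window's label is None (unavailable) when the stream does not cover
    assessment + window minutes.
    """
    n_min = stream.duration_s // 60
    a = assessment_minutes
    labels = {}
    onset = {}
    series = {}
    for outcome, (ch, crosses) in LABEL_RULES.items():
        mm = minute_means(getattr(stream, ch), n_min)
        series[outcome] = crosses(mm)
    if mews is not None:
        series["mews4"] = np.where(
            np.isfinite(mews.total), mews.total >= mews_threshold, False
        )
    for outcome, crossed in series.items():
        post = crossed[a:]
        hit = np.nonzero(post)[0]
        onset[outcome] = int(hit[0]) + 1 if len(hit) else None
        for w in windows:
            if n_min < a + w:
                labels[(outcome, w)] = None
            else:
                labels[(outcome, w)] = bool(post[:w].any())
    return OutcomeLabels(labels=labels, onset_minute=onset)


# ---------------------------------------------------------------------------
# Chronological patient-disjoint splitting
# ---------------------------------------------------------------------------


@dataclass
class SplitAssignment:
    assignment: pd.Series  # visit_id -> {"train", "validation", "test"}
    cutoff_time: float

    def ids(self, part: str) -> list:
        return list(self.assignment.index[self.assignment == part])


def split_cohort(
    visits: pd.DataFrame,
    fractions: tuple = (0.75, 0.125, 0.125),
    seed: int = 0,
) -> SplitAssignment:
    """75/12.5/12.5 chronological, patient-disjoint split.

    The provisional test set is the chronologically latest 12.5 % of
    visits; any patient with visits on both sides of the cutoff has ALL
    visits moved to train (test purity over size).  The earlier visits are
    split into train/validation by seeded patient-grouped assignment.
    """
    req = {"visit_id", "patient_id", "arrival_time"}
    if not req.issubset(visits.columns):
        raise ValueError(f"visits table must have columns {sorted(req)}")
    if visits["patient_id"].nunique() < 3:
        raise ValueError("need at least 3 patients to split")
    df = visits.sort_values("arrival_time", kind="stable").reset_index(drop=True)
    n = len(df)
    n_test = int(round(fractions[2] * n))
    n_test = max(1, n_test)
    cutoff_time = float(df["arrival_time"].iloc[n - n_test])
    test_ids = set(df["visit_id"].iloc[n - n_test :])
    test_patients = set(df["patient_id"].iloc[n - n_test :])
    early_patients = set(df["patient_id"].iloc[: n - n_test])
    straddlers = test_patients & early_patients
    assignment = {}
    for vid, pid in zip(df["visit_id"], df["patient_id"]):
        if vid in test_ids:
            assignment[vid] = "train" if pid in straddlers else "test"

    early = df.iloc[: n - n_test]
    val_target = int(round(fractions[1] * n))
    rng = np.random.default_rng(seed)
    patients = early["patient_id"].unique()
    order = rng.permutation(patients)
    visits_per_patient = early.groupby("patient_id")["visit_id"].apply(list)
    val_count = 0
    val_patients = set()
    for pid in order:
        if val_count >= val_target or pid in straddlers:
            continue
        val_patients.add(pid)
        val_count += len(visits_per_patient[pid])
    for vid, pid in zip(early["visit_id"], early["patient_id"]):
        assignment[vid] = "validation" if pid in val_patients else "train"

    s = pd.Series(assignment, name="split")
    s = s.reindex(visits["visit_id"])
    return SplitAssignment(assignment=s, cutoff_time=cutoff_time)


# ---------------------------------------------------------------------------
# Triage feature encoding
# ---------------------------------------------------------------------------

N_CC = 46
TRIAGE_FEATURE_NAMES = (
    ["age", "gender_female", "gender_male", "esi", "temperature"]
    + ["triage_hr", "triage_rr", "triage_spo2", "triage_map",
       "triage_sbp", "triage_dbp"]
    + [f"cc_{i:02d}" for i in range(1, N_CC + 1)]
)


def encode_triage(record: TriageRecord) -> np.ndarray:
    """Fixed 57-long triage feature vector.

    Layout: age; gender as two indicator columns (female, male); ESI as an
    ordinal; triage temperature; six triage vitals (HR, RR, SpO2, MAP,
    SBP, DBP); 46 one-hot chief-complaint indicators.
    """
    if not 1 <= record.cc_category <= N_CC:
        raise ValueError(
            f"cc_category {record.cc_category} outside 1..{N_CC}"
        )
    cc = np.zeros(N_CC)
    cc[record.cc_category - 1] = 1.0
    head = np.array(
        [
            record.age,
            1.0 if record.gender == "F" else 0.0,
            1.0 if record.gender == "M" else 0.0,
            float(record.esi),
            record.temperature,
            record.hr,
            record.rr,
            record.spo2,
            record.map,
            record.sbp,
            record.dbp,
        ]
    )
    return np.concatenate([head, cc])
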