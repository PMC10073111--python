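"""Inclusion rules, trends, MEWS, outcome labels, splits, triage encoding."""

import numpy as np
import pandas as pd
import pytest

from edecomp.cohort import (
    InclusionRules,
    apply_inclusion,
    compute_mews_series,
    encode_triage,
    label_outcomes,
    minute_trends,
    score_component,
    split_cohort,
    TRIAGE_FEATURE_NAMES,
)
from edecomp.synth import generate_vitals_stream
from edecomp.types import TriageRecord, Visit, VitalStream, WaveformSegment


def _record(**kw):
    base = dict(
        visit_id="v0", patient_id="p0", arrival_time=0.0, age=50, gender="F",
        esi=3, cc_category=7, hr=80, rr=16, spo2=98, sbp=120, dbp=60,
        map=80.0, temperature=37.0,
    )
    base.update(kw)
    return TriageRecord(**base)


def _stream(hr=80.0, rr=14.0, spo2=98.0, map_=90.0, n=8100, sbp=120.0,
            temp=37.0, sbp_times=(0.0,)):
    ones = np.ones(n)
    times = np.asarray(sbp_times, dtype=float)
    return VitalStream(
        hr=hr * ones, rr=rr * ones, spo2=spo2 * ones, map=map_ * ones,
        rr_interval=60000.0 / hr * ones, perfusion_index=1.5 * ones,
        sbp_times=times, sbp_values=np.full(len(times), sbp),
        dbp_times=times, dbp_values=np.full(len(times), sbp - 45.0),
        temperature_times=times, temperature_values=np.full(len(times), temp),
    )


def _wave():
    return WaveformSegment("ecg", 500.0, np.zeros(100))


class TestInclusion:
    def _visit(self, triage=None, vitals=None, with_waves=True):
        return Visit(
            triage=triage or _record(),
            vitals=vitals if vitals is not None else _stream(),
            ecg=_wave() if with_waves else None,
            ppg=WaveformSegment("ppg", 125.0, np.zeros(100)) if with_waves else None,
        )

    def test_elevated_triage_heart_rate_excluded(self):
        res = apply_inclusion(self._visit(triage=_record(hr=112)))
        assert not res.included and res.reason == "HR_TRIAGE"

    def test_assessment_crossing_excluded(self):
        vs = _stream()
        vs.hr[10 * 60] = 111.0  # minute 10 of assessment
        res = apply_inclusion(self._visit(vitals=vs))
        assert not res.included and res.reason == "HR_ASSESSMENT"

    def test_missing_waveform_excluded(self):
        v = self._visit(with_waves=False)
        res = apply_inclusion(v)
        assert not res.included and res.reason == "MISSING_WAVEFORM"

    def test_normal_visit_included(self):
        assert apply_inclusion(self._visit()).included

    def test_boundary_values_are_inclusive(self):
        tri = _record(hr=110, spo2=90, sbp=95, dbp=50, map=65.0)
        assert apply_inclusion(self._visit(triage=tri)).included


class TestTrends:
    def test_constant_channel(self):
        t = minute_trends(_stream(spo2=98.0))
        assert t["spo2"]["slope"] == pytest.approx(0.0)
        assert t["spo2"]["first"] == pytest.approx(98.0)

    def test_exact_line_slope_one(self):
        vs = _stream()
        vs.hr[:900] = np.repeat(np.arange(80.0, 95.0), 60)
        t = minute_trends(vs, assessment_minutes=15)
        assert t["hr"]["slope"] == pytest.approx(1.0)
        assert t["hr"]["first"] == pytest.approx(80.0)

    def test_matches_normal_equation_oracle(self, rng):
        vs = _stream()
        vs.hr[: 15 * 60] = 80 + rng.normal(0, 3, 15 * 60)
        t = minute_trends(vs, 15)
        mm = vs.hr[: 15 * 60].reshape(15, 60).mean(axis=1)
        x = np.arange(15.0)
        beta = (np.sum((x - x.mean()) * (mm - mm.mean()))
                / np.sum((x - x.mean()) ** 2))
        assert t["hr"]["slope"] == pytest.approx(beta, rel=1e-9)

    def test_missing_minutes_dropped(self):
        vs = _stream()
        vs.rr[60:120] = np.nan  # minute 1 fully missing
        t = minute_trends(vs, 15)
        assert t["rr"]["slope"] == pytest.approx(0.0)

    def test_single_minute_slope_missing(self):
        vs = _stream(n=7200)
        vs.map[60:] = np.nan
        t = minute_trends(vs, 15)
        assert t["map"]["slope"] is None


class TestMEWS:
    def test_all_normal_scores_zero(self):
        m = compute_mews_series(_stream(hr=80, rr=12, sbp=120, temp=37.0))
        assert m.total[0] == 0

    def test_respiratory_band_scores_one(self):
        m = compute_mews_series(_stream(hr=80, rr=18, sbp=120, temp=37.0))
        assert m.total[0] == 1

    def test_compound_derangement_scores_seven(self):
        m = compute_mews_series(_stream(hr=115, rr=22, sbp=95, temp=38.6))
        assert m.total[0] == 2 + 2 + 1 + 2

    def test_carry_forward_from_single_observation(self):
        m = compute_mews_series(_stream(sbp=95.0, sbp_times=(0.0,)))
        assert m.components["sbp"][10] == 1  # minute 10 reuses t=0 value
        assert m.carried["sbp"][10]

    def test_carry_forward_idempotent_on_dense_channel(self):
        sparse = compute_mews_series(_stream(sbp=95.0, sbp_times=(0.0,)))
        dense = compute_mews_series(
            _stream(sbp=95.0, sbp_times=tuple(np.arange(0.0, 7200.0, 60.0)))
        )
        assert np.array_equal(sparse.total, dense.total, equal_nan=True)

    def test_total_missing_before_first_observation(self):
        m = compute_mews_series(_stream(sbp_times=(300.0,)))
        assert np.isnan(m.total[:5]).all() and np.isfinite(m.total[5:]).all()

    def test_unobserved_component_rejected(self):
        vs = _stream()
        vs.temperature_times = np.array([])
        vs.temperature_values = np.array([])
        with pytest.raises(ValueError):
            compute_mews_series(vs)

    def test_component_table_spot_values(self):
        assert score_component("hr", 50) == 1
        assert score_component("hr", 51) == 0
        assert score_component("sbp", 70.0) == 3
        assert score_component("sbp", 200.0) == 2
        assert score_component("rr", 30.0) == 3
        assert score_component("temperature", 38.5) == 2


class TestLabels:
    def test_crossing_labels_all_windows(self):
        vs = _stream()
        vs.hr[35 * 60 : 37 * 60] = 111.5  # minute 20 post-assessment
        lab = label_outcomes(vs, compute_mews_series(vs))
        assert lab[("tachycardia", 60)] and lab[("tachycardia", 90)]
        assert lab[("tachycardia", 120)]
        assert lab.onset_minute["tachycardia"] == 21

    def test_boundary_spo2_not_hypoxic(self):
        vs = _stream(spo2=90.0)
        lab = label_outcomes(vs, compute_mews_series(vs))
        assert not any(
            lab[("hypoxia", w)] for w in (60, 90, 120)
        )  # strict < 90

    def test_late_crossing_only_in_longest_window(self):
        vs = _stream(n=8100)
        vs.map[(15 + 99) * 60 : (15 + 101) * 60] = 64.0
        lab = label_outcomes(vs, compute_mews_series(vs))
        assert not lab[("hypotension", 60)]
        assert not lab[("hypotension", 90)]
        assert lab[("hypotension", 120)]

    def test_short_follow_up_unavailable(self):
        vs = _stream(n=(15 + 70) * 60)
        lab = label_outcomes(vs, compute_mews_series(vs))
        assert lab[("tachycardia", 60)] is False
        assert lab[("tachycardia", 90)] is None

    def test_window_nesting_on_synthetic_cohort(self, small_cohort):
        c = small_cohort
        for vid in c.visit_ids[:40]:
            vs = c.vitals[vid]
            lab = label_outcomes(vs, compute_mews_series(vs))
            for outcome in ("tachycardia", "hypoxia", "hypotension", "mews4"):
                assert not (lab[(outcome, 60)] and not lab[(outcome, 90)])
                assert not (lab[(outcome, 90)] and not lab[(outcome, 120)])


class TestSplit:
    def _visits(self, n=1000):
        return pd.DataFrame(
            {
                "visit_id": [f"v{i}" for i in range(n)],
                "patient_id": [f"p{i}" for i in range(n)],
                "arrival_time": np.arange(n, dtype=float),
            }
        )

    def test_exact_sizes_for_single_visit_patients(self):
        sp = split_cohort(self._visits(), seed=0)
        counts = sp.assignment.value_counts()
        assert counts["train"] == 750
        assert counts["validation"] == 125
        assert counts["test"] == 125

    def test_straddling_patient_moved_to_train(self):
        df = self._visits(40)
        # one patient with visits on both sides of the 12.5% cutoff
        df.loc[30, "patient_id"] = "p39"
        sp = split_cohort(df, seed=1)
        assert sp.assignment["v39"] == "train"
        assert sp.assignment["v30"] == "train"

    def test_patient_disjoint_and_chronological(self):
        df = self._visits(400)
        df["patient_id"] = [f"p{i % 180}" for i in range(400)]
        sp = split_cohort(df, seed=2)
        parts = {
            p: set(df.set_index("visit_id").loc[sp.ids(p), "patient_id"])
            for p in ("train", "validation", "test")
        }
        assert not parts["train"] & parts["test"]
        assert not parts["validation"] & parts["test"]
        assert not parts["train"] & parts["validation"]
        test_arrivals = df.set_index("visit_id").loc[sp.ids("test"), "arrival_time"]
        assert (test_arrivals >= sp.cutoff_time).all()

    def test_reproducible(self):
        df = self._visits(300)
        a = split_cohort(df, seed=9).assignment
        b = split_cohort(df, seed=9).assignment
        assert a.equals(b)

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            split_cohort(self._visits(2))


class TestTriageEncoding:
    def test_one_hot_chief_complaint(self):
        v = encode_triage(_record(cc_category=7))
        cc = v[11:]
        assert cc.sum() == 1.0 and cc[6] == 1.0

    def test_map_from_pressures(self):
        v = encode_triage(_record(sbp=120, dbp=60, map=80.0))
        assert v[TRIAGE_FEATURE_NAMES.index("triage_map")] == pytest.approx(80.0)

    def test_schema_length_fixed(self):
        assert len(TRIAGE_FEATURE_NAMES) == 57
        assert len(encode_triage(_record())) == 57

    def test_invalid_chief_complaint_rejected(self):
        rec = _record()
        rec.cc_category = 47
        with pytest.raises(ValueError):
            encode_triage(rec)
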