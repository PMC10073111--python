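"""Evaluation machinery: AUROC, bootstrap, operating points, calibration,
attribution, reclassification, MEWS alignment."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edecomp.evaluation import (
    attribution_summary,
    auroc,
    bootstrap_metrics,
    calibration_isotonic,
    mews_alignment,
    operating_characteristics,
    pick_threshold,
    reclassification_analysis,
)
from edecomp.models import TrainConfig, tune_and_train


def _pair_count_auroc(y, s):
    """Independent oracle: exhaustive concordant-pair enumeration."""
    pos = [v for v, yy in zip(s, y) if yy]
    neg = [v for v, yy in zip(s, y) if not yy]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAUROC:
    def test_four_point_worked_example(self):
        assert auroc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]) == pytest.approx(0.75)

    @given(
        n=st.integers(2, 12),
        seed=st.integers(0, 10**6),
    )
    @settings(max_examples=80, deadline=None)
    def test_rank_equals_pair_counting(self, n, seed):
        rng = np.random.default_rng(seed)
        y = rng.random(n) < 0.5
        if y.all() or not y.any():
            y[0] = ~y[0]
        s = rng.choice(np.linspace(0, 1, 5), n)  # ties likely
        assert auroc(y, s) == pytest.approx(_pair_count_auroc(y, s), rel=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([1, 1], [0.2, 0.4])


class TestBootstrap:
    def test_perfect_separation_degenerate_ci(self):
        y = np.array([0, 0, 0, 1, 1, 1], bool)
        res = bootstrap_metrics(y, y.astype(float), n_replicates=200, seed=0)
        r = res["AUROC"]
        assert r.point == 1.0 and r.ci_low == 1.0 and r.ci_high == 1.0

    def test_paired_identity_delta_zero(self, rng):
        y = rng.random(80) < 0.4
        s = rng.random(80)
        res = bootstrap_metrics(y, s, s, n_replicates=200, seed=1)
        d = res["delta_AUROC"]
        assert d.point == 0.0 and d.ci_low == 0.0 and d.ci_high == 0.0

    def test_ci_brackets_point(self, rng):
        y = rng.random(200) < 0.3
        s = rng.normal(size=200) + y
        res = bootstrap_metrics(y, s, n_replicates=300, seed=2)
        for m in ("AUROC", "AUPRC"):
            r = res[m]
            assert r.ci_low <= r.point <= r.ci_high

    def test_planted_gap_delta_excludes_zero(self, rng):
        n = 1000
        y = rng.random(n) < 0.3
        good = y * 1.6 + rng.normal(size=n)
        bad = y * 0.2 + rng.normal(size=n)
        res = bootstrap_metrics(y, good, bad, n_replicates=400, seed=3)
        assert res["delta_AUROC"].ci_low > 0


class TestOperatingPoint:
    def test_hand_built_confusion(self):
        val_y = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        val_s = [0.9, 0.8, 0.7, 0.2, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1]
        thr = pick_threshold(val_y, val_s, 0.75)
        assert thr == pytest.approx(0.7)
        rep = operating_characteristics(
            val_y, val_s, val_y, val_s, 0.75, n_replicates=50, seed=0
        )
        # at 0.7: TP=3 FN=1 FP=0 TN=6
        assert rep.sensitivity.point == pytest.approx(0.75)
        assert rep.specificity.point == pytest.approx(1.0)
        assert rep.ppv.point == pytest.approx(1.0)
        assert rep.npv.point == pytest.approx(6 / 7)

    def test_threshold_below_all_scores_degenerate(self):
        y = [1, 0, 1, 0]
        s = [0.6, 0.5, 0.9, 0.2]
        rep = operating_characteristics(
            y, s, y, s, target_sensitivity=1.0, n_replicates=50, seed=0
        )
        assert rep.sensitivity.point == 1.0

    def test_separable_validation_transfers(self, rng):
        y = rng.random(300) < 0.4
        s = y + 0.01 * rng.random(300)
        rep = operating_characteristics(y, s, y, s, 0.85, n_replicates=50)
        assert rep.sensitivity.point == 1.0 and rep.specificity.point == 1.0

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pick_threshold([0, 0, 0], [0.1, 0.2, 0.3])


class TestCalibration:
    def test_calibrated_by_construction(self, rng):
        n = 5000
        p = rng.random(n)
        y = rng.random(n) < p
        tab = calibration_isotonic(y[:2500], p[:2500], y[2500:], p[2500:]).table
        assert np.all(np.abs(tab["mean_predicted"] - tab["observed"]) < 0.05)
        assert tab["count"].sum() == 2500

    def test_isotonic_output_monotone(self, rng):
        n = 400
        s = rng.random(n)
        y = rng.random(n) < s
        cal = calibration_isotonic(y, s, y, s)
        grid = np.linspace(0, 1, 101)
        out = cal.isotonic.predict(grid)
        assert np.all(np.diff(out) >= -1e-12)

    def test_constant_predictions_observed_prevalence(self, rng):
        y = rng.random(500) < 0.3
        s = np.full(500, 0.5)
        tab = calibration_isotonic(y, s, y, s).table
        assert np.allclose(tab["mean_predicted"], 0.5)
        pooled = (tab["observed"] * tab["count"]).sum() / tab["count"].sum()
        assert pooled == pytest.approx(y.mean())


def _fitted_bundle(n=500, seed=0, single_feature=False):
    rng = np.random.default_rng(seed)
    cols = ["f1", "f2", "f3"] if not single_feature else ["f1"]
    x = pd.DataFrame({c: rng.normal(size=n) for c in cols})
    y = (x["f1"] + (0 if single_feature else 0.5 * x["f2"].to_numpy())
         + 0.3 * rng.normal(size=n)) > 0
    cfg = TrainConfig(n_tuning_trials=2, n_seeds=1, max_boost_rounds=80)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle = tune_and_train(
            x.iloc[: n // 2], y[: n // 2], x.iloc[n // 2 :], y[n // 2 :],
            cfg, seed=seed,
        )
    return bundle, x, y


class TestAttribution:
    def test_contributions_sum_to_hundred(self):
        bundle, x, _ = _fitted_bundle()
        summary = attribution_summary(bundle, x).table
        assert summary["contribution_pct"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_single_feature_model_gets_everything(self):
        bundle, x, _ = _fitted_bundle(single_feature=True)
        summary = attribution_summary(bundle, x).table
        assert summary.loc[0, "feature"] == "f1"
        assert summary.loc[0, "contribution_pct"] == pytest.approx(100.0)

    def test_monotone_dependence_positive_direction(self):
        bundle, x, _ = _fitted_bundle()
        summary = attribution_summary(bundle, x).table.set_index("feature")
        assert summary.loc["f1", "direction_r"] > 0


class TestReclassification:
    def test_identical_models_empty_report(self, rng):
        y = rng.random(100) < 0.5
        pred = rng.random(100) < 0.5
        feats = pd.DataFrame({"a": rng.normal(size=100)})
        rep = reclassification_analysis(y, pred, pred, feats)
        assert rep.to_positive.empty and rep.to_negative.empty

    def test_planted_shift_detected(self, rng):
        n = 1000
        y = np.ones(n, bool)
        best = np.ones(n, bool)
        baseline = rng.random(n) < 0.8  # ~200 reclassified to positive
        feats = pd.DataFrame({"shifted": rng.normal(0, 1, n),
                              "untouched": rng.normal(0, 1, n)})
        feats.loc[~baseline, "shifted"] += 2.0
        rep = reclassification_analysis(y, baseline, best, feats)
        row = rep.to_positive.set_index("feature").loc["shifted"]
        assert row["p_value"] < 1e-3 and row["scaled_diff"] > 1.5
        null_row = rep.to_positive.set_index("feature").loc["untouched"]
        assert abs(null_row["scaled_diff"]) < 0.3


class TestMEWSAlignment:
    def test_hand_built_two_by_two(self):
        pred = np.array([1] * 8 + [0] * 2 + [1] * 5 + [0] * 15, bool)
        mews = np.array([5] * 10 + [1] * 20)
        out = mews_alignment(pred, mews)
        assert out["prop_high_predicted_positive"] == pytest.approx(0.8)
        assert out["prop_low_predicted_negative"] == pytest.approx(0.75)
        assert out["counts"]["high_pred_pos"] == 8

    def test_degenerate_all_positive(self):
        out = mews_alignment(np.ones(5, bool), np.full(5, 6))
        assert out["prop_high_predicted_positive"] == 1.0
        assert out["prop_low_predicted_negative"] is None

    def test_independence_approaches_marginals(self, rng):
        n = 4000
        pred = rng.random(n) < 0.3
        mews = rng.choice([1, 5], n)
        out = mews_alignment(pred, mews)
        assert out["prop_high_predicted_positive"] == pytest.approx(0.3, abs=0.04)
        assert out["prop_low_predicted_negative"] == pytest.approx(0.7, abs=0.04)
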