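"""Model evaluation: bootstrap CIs, operating points, calibration,
Shapley attribution, reclassification and MEWS-alignment analyses.

AUROC is computed from the Mann-Whitney rank statistic (ties scored 1/2);
AUPRC by precision-recall integration (average precision).  Confidence
intervals are percentile bootstrap; paired AUROC deltas reuse the same
resample indices for both score vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression
from sklearn.metrics import average_precision_score

__all__ = [
    "auroc",
    "auprc",
    "BootstrapResult",
    "bootstrap_metrics",
    "OperatingReport",
    "operating_characteristics",
    "CalibrationTable",
    "calibration_isotonic",
    "AttributionSummary",
    "attribution_summary",
    "ReclassReport",
    "reclassification_analysis",
    "mews_alignment",
]


def auroc(y: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve via the rank-sum statistic.

    Equivalent to the probability that a random positive outscores a
    random negative, with ties counted 1/2.
    """
    y = np.asarray(y, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined for single-class labels")
    ranks = stats.rankdata(scores)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc(y: np.ndarray, scores: np.ndarray) -> float:
    """Area under the precision-recall curve (average precision)."""
    y = np.asarray(y, dtype=int)
    if y.sum() == 0:
        raise ValueError("AUPRC undefined without positives")
    return float(average_precision_score(y, scores))


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    metric: str  # "AUROC" | "AUPRC" | "delta_AUROC"
    point: float
    ci_low: float
    ci_high: float
    n_replicates: int
    seed: int


def _percentile_ci(values: np.ndarray) -> tuple[float, float]:
    return (
        float(np.percentile(values, 2.5)),
        float(np.percentile(values, 97.5)),
    )


def bootstrap_metrics(
    y: np.ndarray,
    scores_a: np.ndarray,
    scores_b: Optional[np.ndarray] = None,
    n_replicates: int = 2000,
    seed: int = 0,
    metrics: tuple = ("AUROC", "AUPRC"),
) -> dict:
    """Percentile bootstrap CIs for AUROC/AUPRC (and the paired delta).

    With ``scores_b`` the AUROC delta (a - b) is computed on the SAME
    resample indices, so its CI reflects the paired comparison.  Replicates
    that draw a single class are redrawn.  2000 replicates is the desk
    default; pass ``n_replicates=10000`` for the full-scale analysis.
    """
    y = np.asarray(y, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("labels contain a single class")
    scores_a = np.asarray(scores_a, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(y)
    reps: dict[str, list] = {m: [] for m in metrics}
    if scores_b is not None:
        scores_b = np.asarray(scores_b, dtype=float)
        reps["delta_AUROC"] = []
    for _ in range(n_replicates):
        idx = rng.integers(0, n, n)
        while y[idx].all() or not y[idx].any():
            idx = rng.integers(0, n, n)
        yb = y[idx]
        if "AUROC" in metrics:
            reps["AUROC"].append(auroc(yb, scores_a[idx]))
        if "AUPRC" in metrics:
            reps["AUPRC"].append(auprc(yb, scores_a[idx]))
        if scores_b is not None:
            reps["delta_AUROC"].append(
                auroc(yb, scores_a[idx]) - auroc(yb, scores_b[idx])
            )
    out = {}
    points = {}
    if "AUROC" in metrics:
        points["AUROC"] = auroc(y, scores_a)
    if "AUPRC" in metrics:
        points["AUPRC"] = auprc(y, scores_a)
    if scores_b is not None:
        points["delta_AUROC"] = auroc(y, scores_a) - auroc(y, scores_b)
    for m, vals in reps.items():
        lo, hi = _percentile_ci(np.asarray(vals))
        out[m] = BootstrapResult(
            metric=m, point=points[m], ci_low=lo, ci_high=hi,
            n_replicates=n_replicates, seed=seed,
        )
    return out


# ---------------------------------------------------------------------------
# Operating points
# ---------------------------------------------------------------------------


@dataclass
class OperatingReport:
    threshold: float
    target_sensitivity: float
    sensitivity: BootstrapResult
    specificity: BootstrapResult
    ppv: BootstrapResult
    npv: BootstrapResult


def pick_threshold(
    val_y: np.ndarray, val_scores: np.ndarray, target_sensitivity: float = 0.85
) -> float:
    """Operating threshold achieving the target sensitivity on validation.

    Predictions are positive where score >= threshold.  Among thresholds
    with sensitivity >= target, the one maximising specificity is chosen;
    specificity ties are broken toward higher sensitivity (the lower
    threshold), so a perfectly separated validation set yields the
    separating cut rather than one inside the positive scores.
    """
    val_y = np.asarray(val_y, dtype=bool)
    scores = np.asarray(val_scores, dtype=float)
    if not val_y.any():
        raise ValueError("validation set has no positives")
    n_pos = int(val_y.sum())
    n_neg = len(val_y) - n_pos
    best = None  # (specificity, sensitivity, threshold)
    for thr in np.unique(scores):
        pred = scores >= thr
        sens = float((pred & val_y).sum()) / n_pos
        if sens < target_sensitivity:
            continue
        spec = float((~pred & ~val_y).sum()) / n_neg if n_neg else 1.0
        if best is None or (spec, sens) > (best[0], best[1]):
            best = (spec, sens, float(thr))
    if best is None:
        raise ValueError(
            f"target sensitivity {target_sensitivity} unattainable"
        )
    return best[2]


def _rates(y: np.ndarray, pred: np.ndarray) -> dict:
    tp = int((pred & y).sum())
    tn = int((~pred & ~y).sum())
    fp = int((pred & ~y).sum())
    fn = int((~pred & y).sum())
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
        "ppv": tp / (tp + fp) if tp + fp else np.nan,
        "npv": tn / (tn + fn) if tn + fn else np.nan,
    }


def operating_characteristics(
    val_y: np.ndarray,
    val_scores: np.ndarray,
    test_y: np.ndarray,
    test_scores: np.ndarray,
    target_sensitivity: float = 0.85,
    n_replicates: int = 2000,
    seed: int = 0,
) -> OperatingReport:
    """Freeze the 0.85-sensitivity threshold on validation, report test
    sensitivity/specificity/PPV/NPV with bootstrap CIs."""
    thr = pick_threshold(val_y, val_scores, target_sensitivity)
    test_y = np.asarray(test_y, dtype=bool)
    test_scores = np.asarray(test_scores, dtype=float)
    pred = test_scores >= thr
    point = _rates(test_y, pred)
    rng = np.random.default_rng(seed)
    n = len(test_y)
    reps = {k: [] for k in point}
    for _ in range(n_replicates):
        idx = rng.integers(0, n, n)
        r = _rates(test_y[idx], pred[idx])
        for k in reps:
            reps[k].append(r[k])
    results = {}
    for k in point:
        vals = np.asarray(reps[k], dtype=float)
        vals = vals[np.isfinite(vals)]
        lo, hi = _percentile_ci(vals) if len(vals) else (np.nan, np.nan)
        results[k] = BootstrapResult(
            metric=k, point=point[k], ci_low=lo, ci_high=hi,
            n_replicates=n_replicates, seed=seed,
        )
    return OperatingReport(
        threshold=thr, target_sensitivity=target_sensitivity, **results
    )


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


@dataclass
class CalibrationTable:
    table: pd.DataFrame  # bin, mean_predicted, observed, count, mean_adjusted
    isotonic: IsotonicRegression


def calibration_isotonic(
    val_y: np.ndarray,
    val_scores: np.ndarray,
    test_y: np.ndarray,
    test_scores: np.ndarray,
    n_bins: int = 5,
) -> CalibrationTable:
    """Equal-count prediction quintiles on test + isotonic recalibration.

    Ties are broken by stable order (score, then position); the isotonic
    map is fit on the validation set and applied to the test predictions.
    """
    test_y = np.asarray(test_y, dtype=float)
    test_scores = np.asarray(test_scores, dtype=float)
    n = len(test_scores)
    if n < n_bins:
        raise ValueError("need at least one observation per bin")
    iso = IsotonicRegression(out_of_bounds="clip", y_min=0.0, y_max=1.0)
    iso.fit(np.asarray(val_scores, dtype=float), np.asarray(val_y, dtype=float))
    adjusted = iso.predict(test_scores)
    order = np.argsort(test_scores, kind="stable")
    bins = np.array_split(order, n_bins)
    rows = []
    for b, idx in enumerate(bins):
        rows.append(
            {
                "bin": b + 1,
                "mean_predicted": float(test_scores[idx].mean()),
                "observed": float(test_y[idx].mean()),
                "count": len(idx),
                "mean_adjusted": float(adjusted[idx].mean()),
            }
        )
    return CalibrationTable(table=pd.DataFrame(rows), isotonic=iso)


# ---------------------------------------------------------------------------
# Shapley attribution
# ---------------------------------------------------------------------------


@dataclass
class AttributionSummary:
    table: pd.DataFrame  # feature, contribution_pct, direction_r


def attribution_summary(bundle, x: pd.DataFrame) -> AttributionSummary:
    """Exact tree-path Shapley attribution for a fitted ensemble.

    Contribution % is each feature's mean |Shapley value| normalised to
    sum to 100; direction is the Pearson correlation between the feature's
    values and its Shapley values (missing for zero-variance inputs).
    """
    from .models import _align  # local import avoids a cycle

    x = _align(bundle, x)
    contrib = bundle.model.predict(
        x, pred_contrib=True, num_iteration=bundle.best_iteration
    )
    shap_vals = contrib[:, :-1]  # last column is the bias term
    mean_abs = np.abs(shap_vals).mean(axis=0)
    total = mean_abs.sum()
    pct = 100.0 * mean_abs / total if total > 0 else np.zeros_like(mean_abs)
    rs = []
    xv = x.to_numpy(dtype=float)
    for j in range(x.shape[1]):
        col = xv[:, j]
        ok = np.isfinite(col)
        if ok.sum() < 2 or np.std(col[ok]) == 0 or np.std(shap_vals[ok, j]) == 0:
            rs.append(np.nan)
        else:
            rs.append(float(stats.pearsonr(col[ok], shap_vals[ok, j])[0]))
    table = pd.DataFrame(
        {
            "feature": list(x.columns),
            "contribution_pct": pct,
            "direction_r": rs,
        }
    ).sort_values("contribution_pct", ascending=False, kind="stable")
    return AttributionSummary(table=table.reset_index(drop=True))


# ---------------------------------------------------------------------------
# Reclassification
# ---------------------------------------------------------------------------


@dataclass
class ReclassReport:
    to_positive: pd.DataFrame  # feature, scaled_diff, p_value, n_reclassified
    to_negative: pd.DataFrame


def _reclass_table(
    features: pd.DataFrame, mask_reclass: np.ndarray
) -> pd.DataFrame:
    rows = []
    n_re = int(mask_reclass.sum())
    for col in features.columns:
        v = features[col].to_numpy(dtype=float)
        a = v[mask_reclass]
        b = v[~mask_reclass]
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if len(a) < 2 or len(b) < 2 or np.std(b, ddof=1) == 0:
            continue
        scaled = (a.mean() - b.mean()) / np.std(b, ddof=1)
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
        rows.append(
            {"feature": col, "scaled_diff": float(scaled),
             "p_value": float(p), "n_reclassified": n_re}
        )
    return pd.DataFrame(rows, columns=["feature", "scaled_diff", "p_value",
                                       "n_reclassified"])


def reclassification_analysis(
    y: np.ndarray,
    baseline_pred: np.ndarray,
    best_pred: np.ndarray,
    features: pd.DataFrame,
) -> ReclassReport:
    """Compare reclassified visits against the rest, per direction.

    Reclassified-to-positive: outcome positive, best model correct,
    baseline wrong; to-negative symmetrically.  Mean feature differences
    are scaled by the non-reclassified SD; p-values are Welch two-sided
    t-tests.  Empty cohorts yield empty (zero-row) tables.
    """
    y = np.asarray(y, dtype=bool)
    baseline_pred = np.asarray(baseline_pred, dtype=bool)
    best_pred = np.asarray(best_pred, dtype=bool)
    to_pos = y & best_pred & ~baseline_pred
    to_neg = ~y & ~best_pred & baseline_pred
    return ReclassReport(
        to_positive=_reclass_table(features, to_pos) if to_pos.any()
        else _reclass_table(features, to_pos).iloc[0:0],
        to_negative=_reclass_table(features, to_neg) if to_neg.any()
        else _reclass_table(features, to_neg).iloc[0:0],
    )


# ---------------------------------------------------------------------------
# MEWS alignment
# ---------------------------------------------------------------------------


def mews_alignment(
    predicted_positive: np.ndarray,
    max_mews: np.ndarray,
    mews_threshold: int = 4,
) -> dict:
    """Agreement between dichotomous predictions and the composite score.

    Returns the proportion of visits reaching MEWS >= 4 that were
    predicted to decompensate, the proportion with maximum MEWS < 4
    predicted not to, and the underlying 2x2 counts.  A proportion is None
    when its denominator group is empty.
    """
    pred = np.asarray(predicted_positive, dtype=bool)
    high = np.asarray(max_mews, dtype=float) >= mews_threshold
    counts = {
        "high_pred_pos": int((high & pred).sum()),
        "high_pred_neg": int((high & ~pred).sum()),
        "low_pred_pos": int((~high & pred).sum()),
        "low_pred_neg": int((~high & ~pred).sum()),
    }
    n_high = counts["high_pred_pos"] + counts["high_pred_neg"]
    n_low = counts["low_pred_pos"] + counts["low_pred_neg"]
    if n_high == 0:
        warnings.warn("no visits reached the MEWS threshold")
    return {
        "prop_high_predicted_positive": (
            counts["high_pred_pos"] / n_high if n_high else None
        ),
        "prop_low_predicted_negative": (
            counts["low_pred_neg"] / n_low if n_low else None
        ),
        "counts": counts,
    }
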