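"""Gradient-boosted decision-tree risk models over ablatable feature sets.

A feature set is a named subset of six groups (triage, vital-sign trends,
PAT, HRV, perfusion, waveform embeddings).  For each prediction task,
window and feature set, a LightGBM classifier is tuned by seeded random
search (validation AUROC objective) and then refit across a sweep of
ensemble random seeds with early stopping, keeping the seed with the best
validation AUROC (ties broken by the lower seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import lightgbm as lgb
import numpy as np
import pandas as pd

from .cohort import TRIAGE_FEATURE_NAMES
from .evaluation import auroc
from .features import HRV_FIELDS

__all__ = [
    "FeatureSetSpec",
    "TrainConfig",
    "ModelBundle",
    "GROUP_COLUMNS",
    "TRIAGE_ONLY",
    "FULL",
    "assemble_feature_matrix",
    "tune_and_train",
    "predict_risk",
]

#: canonical column membership of each feature group
GROUP_COLUMNS = {
    "triage": list(TRIAGE_FEATURE_NAMES),
    "vs_trends": [
        "hr_first", "rr_first", "spo2_first", "map_first",
        "sbp_first", "dbp_first",
        "hr_slope", "rr_slope", "spo2_slope", "map_slope",
    ],
    "pat": ["pat_mean"],
    "hrv": list(HRV_FIELDS),
    "perfusion": ["perfusion_index"],
    "embeddings": [f"ecg_e{i}" for i in range(1, 5)]
    + [f"ppg_e{i}" for i in range(1, 5)],
}


@dataclass
class FeatureSetSpec:
    """A named ablation: which feature groups enter the model."""

    name: str
    groups: tuple

    def __post_init__(self) -> None:
        unknown = set(self.groups) - set(GROUP_COLUMNS)
        if unknown:
            raise ValueError(f"unknown feature groups: {sorted(unknown)}")

    @property
    def columns(self) -> list:
        cols = []
        for g in ("triage", "vs_trends", "pat", "hrv", "perfusion", "embeddings"):
            if g in self.groups:
                cols.extend(GROUP_COLUMNS[g])
        return cols


TRIAGE_ONLY = FeatureSetSpec("triage", ("triage",))
FULL = FeatureSetSpec(
    "full", ("triage", "vs_trends", "pat", "hrv", "perfusion", "embeddings")
)


def assemble_feature_matrix(
    features: pd.DataFrame, feature_set: FeatureSetSpec
) -> pd.DataFrame:
    """Select the feature-set columns in canonical order.

    ``features`` is a per-visit table holding (a superset of) the group
    columns; engineered features may be NaN (e.g. failed waveform QC) and
    the row is retained — LightGBM routes missing values natively.
    Requesting a group whose columns were never computed is an error.
    """
    cols = feature_set.columns
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise ValueError(
            f"feature set {feature_set.name!r} needs uncomputed columns: "
            f"{missing[:5]}..." if len(missing) > 5 else
            f"feature set {feature_set.name!r} needs uncomputed columns: {missing}"
        )
    return features[cols].astype(float)


@dataclass
class TrainConfig:
    """Tuning/selection budget.  Desk defaults are 20 trials / 10 seeds;
    the full-scale protocol is 100 / 100."""

    n_tuning_trials: int = 20
    n_seeds: int = 10
    early_stopping_rounds: int = 50
    max_boost_rounds: int = 400
    min_val_positives_warn: int = 20

    def __post_init__(self) -> None:
        if self.n_seeds < 1 or self.early_stopping_rounds < 1:
            raise ValueError("n_seeds and early_stopping_rounds must be >= 1")


#: random-search space (log-uniform where noted)
SEARCH_SPACE = {
    "num_leaves": (15, 255),
    "max_depth": (3, 12),
    "learning_rate": (0.01, 0.3),  # log-uniform
    "min_child_samples": (5, 100),
    "feature_fraction": (0.5, 1.0),
    "bagging_fraction": (0.5, 1.0),
    "lambda_l1": (0.0, 5.0),
    "lambda_l2": (0.0, 5.0),
}


def _sample_params(rng: np.random.Generator) -> dict:
    lo, hi = SEARCH_SPACE["learning_rate"]
    return {
        "num_leaves": int(rng.integers(*SEARCH_SPACE["num_leaves"])),
        "max_depth": int(rng.integers(*SEARCH_SPACE["max_depth"])),
        "learning_rate": float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
        "min_child_samples": int(rng.integers(*SEARCH_SPACE["min_child_samples"])),
        "feature_fraction": float(rng.uniform(*SEARCH_SPACE["feature_fraction"])),
        "bagging_fraction": float(rng.uniform(*SEARCH_SPACE["bagging_fraction"])),
        "bagging_freq": 1,
        "lambda_l1": float(rng.uniform(*SEARCH_SPACE["lambda_l1"])),
        "lambda_l2": float(rng.uniform(*SEARCH_SPACE["lambda_l2"])),
    }


@dataclass
class ModelBundle:
    """A fitted ensemble plus everything needed to reuse it safely."""

    model: lgb.Booster
    feature_names: list
    params: dict
    winning_seed: int
    val_auroc: float
    task: str = ""
    window: int = 0
    feature_set: Optional[FeatureSetSpec] = None
    seed_aurocs: dict = field(default_factory=dict)

    @property
    def best_iteration(self) -> int:
        return self.model.best_iteration or 0


def _fit_once(
    x_tr: pd.DataFrame,
    y_tr: np.ndarray,
    x_val: pd.DataFrame,
    y_val: np.ndarray,
    params: dict,
    seed: int,
    cfg: TrainConfig,
) -> tuple[lgb.Booster, float]:
    full = {
        "objective": "binary",
        "metric": "auc",
        "verbosity": -1,
        "seed": seed,
        "deterministic": True,
        "force_row_wise": True,
        **params,
    }
    dtrain = lgb.Dataset(x_tr, label=y_tr, free_raw_data=False)
    dval = lgb.Dataset(x_val, label=y_val, reference=dtrain, free_raw_data=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        booster = lgb.train(
            full,
            dtrain,
            num_boost_round=cfg.max_boost_rounds,
            valid_sets=[dval],
            callbacks=[
                lgb.early_stopping(cfg.early_stopping_rounds, verbose=False),
                lgb.log_evaluation(period=0),
            ],
        )
    scores = booster.predict(x_val, num_iteration=booster.best_iteration)
    return booster, auroc(y_val, scores)


def tune_and_train(
    x_train: pd.DataFrame,
    y_train: np.ndarray,
    x_val: pd.DataFrame,
    y_val: np.ndarray,
    config: Optional[TrainConfig] = None,
    seed: int = 0,
    task: str = "",
    window: int = 0,
    feature_set: Optional[FeatureSetSpec] = None,
) -> ModelBundle:
    """Random-search hyperparameters, then sweep the ensemble seed.

    Both stages select on validation AUROC; the seed sweep refits the best
    hyperparameters ``n_seeds`` times varying only LightGBM's random seed
    (early stopping on validation) and keeps the best run.
    """
    cfg = config or TrainConfig()
    y_train = np.asarray(y_train, dtype=int)
    y_val = np.asarray(y_val, dtype=int)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training labels contain a single class")
    if len(np.unique(y_val)) < 2:
        raise ValueError("validation labels contain a single class")
    if y_val.sum() < cfg.min_val_positives_warn:
        warnings.warn(
            f"validation set has only {int(y_val.sum())} positives; "
            "AUROC-based selection will be noisy"
        )
    if list(x_train.columns) != list(x_val.columns):
        raise ValueError("train/validation feature schemas differ")
    rng = np.random.default_rng(seed)
    best_params, best_auc = None, -np.inf
    for _ in range(cfg.n_tuning_trials):
        params = _sample_params(rng)
        _, auc = _fit_once(x_train, y_train, x_val, y_val, params, seed, cfg)
        if auc > best_auc:
            best_params, best_auc = params, auc
    assert best_params is not None

    seed_aurocs = {}
    best_model, best_seed, best_auc = None, None, -np.inf
    for k in range(cfg.n_seeds):
        s = seed + k
        booster, auc = _fit_once(x_train, y_train, x_val, y_val, best_params, s, cfg)
        seed_aurocs[s] = auc
        if auc > best_auc:  # strict: ties keep the earlier (lower) seed
            best_model, best_seed, best_auc = booster, s, auc
    return ModelBundle(
        model=best_model,
        feature_names=list(x_train.columns),
        params=best_params,
        winning_seed=best_seed,
        val_auroc=best_auc,
        task=task,
        window=window,
        feature_set=feature_set,
        seed_aurocs=seed_aurocs,
    )


def _align(bundle: ModelBundle, x: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in bundle.feature_names if c not in x.columns]
    extra = [c for c in x.columns if c not in bundle.feature_names]
    if missing or extra:
        raise ValueError(
            f"feature schema mismatch: missing={missing}, unexpected={extra}"
        )
    return x[bundle.feature_names].astype(float)


def predict_risk(bundle: ModelBundle, x: pd.DataFrame) -> np.ndarray:
    """Event probabilities in [0, 1]; missing cells use native routing."""
    aligned = _align(bundle, x)
    p = bundle.model.predict(aligned, num_iteration=bundle.best_iteration)
    return np.clip(np.asarray(p, dtype=float), 0.0, 1.0)
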