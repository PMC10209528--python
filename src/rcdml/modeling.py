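"""Tree-ensemble classifiers and random-search hyperparameter optimisation.

Three interchangeable algorithms share a single train/predict contract:

* ``rf``   — random forest (scikit-learn),
* ``gb_a`` — gradient boosting with per-level column subsampling and a
  min-split-loss (gamma) term (XGBoost),
* ``gb_b`` — gradient boosting without those two knobs (LightGBM).

``DEFAULT_GRIDS`` holds the full reference search space; ``DESK_GRIDS``
is a subset of the same values trimmed for single-CPU runs (fewer, smaller
ensembles) and is what the test-suite and the acceptance script search over.
Random search samples each grid entry uniformly and independently, scores a
configuration by mean ROC-AUC over stratified CV folds shared across all
configurations, and keeps the first-sampled best.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .evaluation import roc_auc

__all__ = [
    "ALGORITHMS",
    "DEFAULT_GRIDS",
    "DESK_GRIDS",
    "ClassifierSpec",
    "TrainedModel",
    "CvResult",
    "sample_param_configs",
    "random_search",
    "search_over_folds",
    "fit",
    "predict_scores",
]

ALGORITHMS = ("rf", "gb_a", "gb_b")

_DEPTHS = [10, 20, 30, 40, 50, 60, 70, 80, 90, 100, 110, None]
_N_EST = [100, 150, 200, 250, 500, 750, 1000]

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "rf": {
        "bootstrap": [True, False],
        "max_depth": list(_DEPTHS),
        "max_features": ["auto", "sqrt"],
        "min_samples_leaf": [1, 2, 4],
        "min_samples_split": [2, 5, 10],
        "n_estimators": list(_N_EST),
    },
    "gb_a": {
        "max_depth": list(_DEPTHS),
        "learning_rate": [0.001, 0.01, 0.1, 0.2, 0.3],
        "subsample": [0.5, 0.6, 0.7, 0.8, 0.9, 1.0],
        "colsample_bytree": [0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0],
        "colsample_bylevel": [0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0],
        "min_child_weight": [0.5, 1.0, 3.0, 5.0, 7.0, 10.0],
        "gamma": [0, 0.25, 0.5, 1.0],
        "reg_lambda": [0.1, 1.0, 5.0, 10.0, 50.0, 100.0],
        "n_estimators": list(_N_EST),
    },
    "gb_b": {
        "max_depth": list(_DEPTHS),
        "learning_rate": [0.001, 0.01, 0.1, 0.2, 0.3],
        "subsample": [0.5, 0.6, 0.7, 0.8, 0.9, 1.0],
        "colsample_bytree": [0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0],
        "min_child_weight": [0.5, 1.0, 3.0, 5.0, 7.0, 10.0],
        "reg_lambda": [0.1, 1.0, 5.0, 10.0, 50.0, 100.0],
        "n_estimators": list(_N_EST),
    },
}

# single-CPU search space: value subsets of the full grids
DESK_GRIDS: dict[str, dict[str, list]] = {
    "rf": {
        "bootstrap": [True, False],
        "max_depth": [10, 30, None],
        "max_features": ["sqrt"],
        "min_samples_leaf": [1, 2, 4],
        "min_samples_split": [2, 5, 10],
        "n_estimators": [100, 200],
    },
    "gb_a": {
        "max_depth": [10, 30, None],
        "learning_rate": [0.01, 0.1, 0.3],
        "subsample": [0.7, 1.0],
        "colsample_bytree": [0.5, 0.8, 1.0],
        "colsample_bylevel": [0.5, 1.0],
        "min_child_weight": [0.5, 1.0, 5.0],
        "gamma": [0, 0.5],
        "reg_lambda": [0.1, 1.0, 10.0],
        "n_estimators": [100, 200],
    },
    "gb_b": {
        "max_depth": [10, 30, None],
        "learning_rate": [0.01, 0.1, 0.3],
        "subsample": [0.7, 1.0],
        "colsample_bytree": [0.5, 0.8, 1.0],
        "min_child_weight": [0.5, 1.0, 5.0],
        "reg_lambda": [0.1, 1.0, 10.0],
        "n_estimators": [100, 200],
    },
}


@dataclass
class ClassifierSpec:
    algorithm: str
    param_grid: dict[str, list] | None = None
    n_iter: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.param_grid is None:
            self.param_grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.algorithm].items()}
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


@dataclass
class TrainedModel:
    algorithm: str
    params: dict
    model: object
    feature_schema: list[str]

    def _check_schema(self, X: pd.DataFrame) -> None:
        if list(X.columns) != self.feature_schema:
            raise ValueError(
                "feature schema mismatch: model expects "
                f"{self.feature_schema[:5]}... got {list(X.columns)[:5]}..."
            )


@dataclass
class CvResult:
    fold_aucs: list[float]
    best_params: dict
    n_folds: int = 5

    def __post_init__(self) -> None:
        if len(self.fold_aucs) != self.n_folds:
            raise ValueError("fold count mismatch")

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))


def _build_estimator(algorithm: str, params: dict, seed: int):
    p = dict(params)
    if algorithm == "rf":
        if p.get("max_features") == "auto":  # pre-1.1 sklearn token for sqrt(p)
            p["max_features"] = "sqrt"
        return RandomForestClassifier(random_state=seed, n_jobs=1, **p)
    if algorithm == "gb_a":
        from xgboost import XGBClassifier

        if p.get("max_depth") is None:
            p["max_depth"] = 0  # no depth limit under hist
        return XGBClassifier(
            random_state=seed, n_jobs=1, tree_method="hist", eval_metric="logloss", **p
        )
    if algorithm == "gb_b":
        from lightgbm import LGBMClassifier

        if p.get("max_depth") is None:
            p["max_depth"] = -1  # LightGBM's no-limit token
        if p.get("subsample", 1.0) < 1.0:
            p.setdefault("subsample_freq", 1)  # bagging is off unless freq > 0
        return LGBMClassifier(
            random_state=seed, n_jobs=1, verbose=-1, deterministic=True,
            force_row_wise=True, **p,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


def sample_param_configs(spec: ClassifierSpec) -> list[dict]:
    """n_iter configurations sampled uniformly from the grid, de-duplicated."""
    rng = np.random.default_rng(spec.seed)
    seen: set[tuple] = set()
    configs: list[dict] = []
    for _ in range(spec.n_iter):
        cfg = {k: v[rng.integers(len(v))] for k, v in spec.param_grid.items()}
        key = tuple(sorted((k, repr(v)) for k, v in cfg.items()))
        if key not in seen:
            seen.add(key)
            configs.append(cfg)
    return configs


def _fold_auc(model, X_val: pd.DataFrame, y_val: np.ndarray) -> float:
    if len(np.unique(y_val)) < 2:
        warnings.warn("single-class validation fold: AUC undefined, scored as 0.5")
        return 0.5
    return roc_auc(model.predict_proba(X_val.to_numpy())[:, 1], y_val)


def search_over_folds(
    spec: ClassifierSpec,
    fold_data: Sequence[tuple[pd.DataFrame, np.ndarray, pd.DataFrame, np.ndarray]],
) -> tuple[dict, CvResult]:
    """Random search over pre-built (X_train, y_train, X_val, y_val) folds.

    The folds are shared across configurations (so scores are comparable);
    the winning configuration is the first-sampled one with the highest mean
    fold AUC.
    """
    configs = sample_param_configs(spec)
    best: tuple[float, list[float], dict] | None = None
    for cfg in configs:
        aucs: list[float] = []
        for X_tr, y_tr, X_val, y_val in fold_data:
            est = _build_estimator(spec.algorithm, cfg, spec.seed)
            est.fit(X_tr.to_numpy(), np.asarray(y_tr))
            aucs.append(_fold_auc(est, X_val, np.asarray(y_val)))
        mean = float(np.mean(aucs))
        if best is None or mean > best[0]:
            best = (mean, aucs, cfg)
    assert best is not None
    _, aucs, cfg = best
    return cfg, CvResult(fold_aucs=aucs, best_params=cfg, n_folds=len(fold_data))


def random_search(
    spec: ClassifierSpec,
    X: pd.DataFrame,
    y: Sequence[int] | np.ndarray,
    folds: int = 5,
) -> tuple[dict, CvResult]:
    """Random search with an internal stratified k-fold split of (X, y)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if len(y) < folds:
        raise ValueError("fewer samples than folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.seed)
    fold_data = [
        (X.iloc[tr], y[tr], X.iloc[va], y[va]) for tr, va in skf.split(X, y)
    ]
    return search_over_folds(spec, fold_data)


def fit(
    algorithm: str,
    params: dict,
    X: pd.DataFrame,
    y: Sequence[int] | np.ndarray,
    seed: int = 0,
) -> TrainedModel:
    """Fit one classifier with fixed hyperparameters; reproducible given the seed."""
    y = np.asarray(y)
    est = _build_estimator(algorithm, params, seed)
    est.fit(X.to_numpy(), y)
    return TrainedModel(
        algorithm=algorithm, params=dict(params), model=est, feature_schema=list(X.columns)
    )


def predict_scores(model: TrainedModel, X: pd.DataFrame) -> np.ndarray:
    """Class-1 probability per sample (vote fraction for RF, logistic margin for GB)."""
    model._check_schema(X)
    if len(X) == 0:
        return np.zeros(0)
    return model.model.predict_proba(X.to_numpy())[:, 1]
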