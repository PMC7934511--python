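"""Model lab: feature selection, grid-search tuning, training and P_low prediction.

Every candidate is a (feature-selection setting × algorithm × parameter
set) combination evaluated by stratified 10-fold cross-validation;
feature selection is fitted inside each training fold only.  Candidates
are ranked by mean CV auROC with ties broken by lower Brier loss, then
fewer retained features, then lexicographic spec.  The winning spec can
be refitted on all rows (:func:`train_final`) yielding a
:class:`TunedModel` that predicts ``P_low``, the probability that a
sample is of low quality.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.feature_selection import RFE, SelectKBest, chi2 as chi2_score
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_validate
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from seqqc.features import FeatureMatrix
from seqqc.grids import expand_grid, load_grid

__all__ = [
    "ModelSpec",
    "TunedModel",
    "GridResult",
    "ALGORITHMS",
    "ADMITTED_K",
    "select_features",
    "grid_search",
    "train_final",
    "predict",
    "brier",
]

ADMITTED_K = (0.25, 0.5, 0.75, 1.0)
_SELECTION_METHODS = ("none", "chi2", "rfe", "stability")

#: The ten classifier families of the default model lab (XGBoost is an
#: optional plug-in, excluded from the shipped default grid).
ALGORITHMS = (
    "decision_tree",
    "random_forest",
    "gradient_boosting",
    "xgboost",
    "adaboost",
    "mlp",
    "naive_bayes",
    "knn",
    "svm",
    "logistic_regression",
)


@dataclass(frozen=True)
class ModelSpec:
    """Classifier family + parameters + feature-selection setting."""

    algorithm: str
    params: dict = field(default_factory=dict)
    selection: str = "none"
    k_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")
        if self.selection not in _SELECTION_METHODS:
            raise ValueError(f"unknown selection method {self.selection!r}")
        if not any(math.isclose(self.k_fraction, k) for k in ADMITTED_K):
            raise ValueError(f"k_fraction must be one of {ADMITTED_K}")

    def key(self) -> str:
        params = json.dumps(self.params, sort_keys=True, default=str)
        return f"{self.selection}@{self.k_fraction:g}|{self.algorithm}|{params}"

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "params": dict(self.params),
            "selection": self.selection,
            "k_fraction": self.k_fraction,
        }


def _make_estimator(spec: ModelSpec, seed: int) -> BaseEstimator:
    p = {k: (list(v) if isinstance(v, tuple) else v) for k, v in spec.params.items()}
    if spec.algorithm == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **p)
    if spec.algorithm == "random_forest":
        return RandomForestClassifier(random_state=seed, **p)
    if spec.algorithm == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **p)
    if spec.algorithm == "adaboost":
        return AdaBoostClassifier(random_state=seed, **p)
    if spec.algorithm == "mlp":
        if "hidden_layer_sizes" in p:
            p["hidden_layer_sizes"] = tuple(p["hidden_layer_sizes"])
        return MLPClassifier(random_state=seed, **p)
    if spec.algorithm == "naive_bayes":
        return GaussianNB(**p)
    if spec.algorithm == "knn":
        return KNeighborsClassifier(**p)
    if spec.algorithm == "svm":
        return SVC(probability=True, random_state=seed, **p)
    if spec.algorithm == "logistic_regression":
        return LogisticRegression(random_state=seed, **p)
    if spec.algorithm == "xgboost":
        try:
            from xgboost import XGBClassifier
        except ImportError as exc:  # pragma: no cover
            raise ImportError("xgboost plug-in requested but the package is not installed") from exc
        return XGBClassifier(random_state=seed, **p)
    raise ValueError(spec.algorithm)


def _k_of(k_fraction: float, n_columns: int) -> int:
    return max(1, math.ceil(k_fraction * n_columns))


class FeatureSelector(BaseEstimator, TransformerMixin):
    """Top-k feature selection transformer (none / chi2 / RFE / stability).

    Used inside cross-validation pipelines so selection only ever sees
    training-fold data.  ``stability`` ranks features by how often an
    L1-penalized logistic model assigns them non-zero weight across 100
    random half-subsamples.
    """

    def __init__(self, method: str = "none", k_fraction: float = 1.0, seed: int = 0,
                 n_resamples: int = 100, subsample: float = 0.5, l1_C: float = 1.0):
        self.method = method
        self.k_fraction = k_fraction
        self.seed = seed
        self.n_resamples = n_resamples
        self.subsample = subsample
        self.l1_C = l1_C

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n_cols = X.shape[1]
        k = _k_of(self.k_fraction, n_cols)
        if self.method == "none" or k >= n_cols:
            self.support_ = np.ones(n_cols, dtype=bool)
            return self
        if self.method == "chi2":
            if np.any(X < 0):
                raise ValueError("chi2 feature selection requires non-negative feature values")
            sel = SelectKBest(chi2_score, k=k).fit(X, y)
            self.support_ = sel.get_support()
        elif self.method == "rfe":
            est = LogisticRegression(max_iter=1000, random_state=self.seed)
            self.support_ = RFE(est, n_features_to_select=k, step=0.25).fit(X, y).support_
        elif self.method == "stability":
            rng = np.random.default_rng(self.seed)
            freq = np.zeros(n_cols)
            n_sub = max(2, int(self.subsample * len(y)))
            for _ in range(self.n_resamples):
                idx = rng.choice(len(y), size=n_sub, replace=False)
                if len(np.unique(y[idx])) < 2:
                    continue
                m = LogisticRegression(
                    l1_ratio=1.0, solver="liblinear", C=self.l1_C, random_state=self.seed
                ).fit(X[idx], y[idx])
                freq += (np.abs(m.coef_[0]) > 1e-8)
            order = np.lexsort((np.arange(n_cols), -freq))  # ties: earlier column wins
            self.support_ = np.zeros(n_cols, dtype=bool)
            self.support_[order[:k]] = True
        else:
            raise ValueError(f"unknown selection method {self.method!r}")
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float)[:, self.support_]


def select_features(
    matrix: FeatureMatrix | pd.DataFrame,
    labels: Sequence[int],
    method: str = "none",
    k_fraction: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Retain the top ``ceil(k_fraction × n_columns)`` features.

    Returns the reduced table and the record of selected column names.
    Deterministic under a fixed seed.  ``chi2`` raises on negative
    feature values.
    """
    if method not in _SELECTION_METHODS:
        raise ValueError(f"unknown selection method {method!r}")
    if not any(math.isclose(k_fraction, k) for k in ADMITTED_K):
        raise ValueError(f"k_fraction must be one of {ADMITTED_K}")
    df = matrix.df if isinstance(matrix, FeatureMatrix) else matrix
    y = np.asarray(labels)
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary")
    sel = FeatureSelector(method=method, k_fraction=k_fraction, seed=seed).fit(df.to_numpy(), y)
    cols = [c for c, keep in zip(df.columns, sel.support_) if keep]
    return df[cols], cols


def _fingerprint(df: pd.DataFrame, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(",".join(map(str, df.index)).encode())
    h.update(",".join(df.columns).encode())
    h.update(np.ascontiguousarray(df.to_numpy(float)).tobytes())
    h.update(np.ascontiguousarray(np.asarray(y, dtype=np.int64)).tobytes())
    return h.hexdigest()


_SCORERS = {
    "auroc": "roc_auc",
    "auprc": "average_precision",
    "accuracy": "accuracy",
    "f1": "f1",
    "brier": "neg_brier_score",
}


@dataclass
class GridResult:
    """One grid-search candidate with its cross-validated metrics."""

    spec: ModelSpec
    cv_metrics: dict[str, dict[str, float]]  # metric -> {mean, sd}
    n_features: int
    folds: int

    @property
    def auroc(self) -> float:
        return self.cv_metrics["auroc"]["mean"]

    @property
    def brier(self) -> float:
        return self.cv_metrics["brier"]["mean"]


def _build_pipeline(spec: ModelSpec, seed: int) -> Pipeline:
    return Pipeline(
        [
            ("select", FeatureSelector(method=spec.selection, k_fraction=spec.k_fraction, seed=seed)),
            ("clf", _make_estimator(spec, seed)),
        ]
    )


def grid_search(
    matrix: FeatureMatrix | pd.DataFrame,
    labels: Sequence[int],
    grid: dict | list[ModelSpec] | None = None,
    folds: int = 10,
    seed: int = 0,
    n_jobs: int = 1,
) -> list[GridResult]:
    """Score every grid combination by stratified ``folds``-fold CV.

    ``grid`` may be a config dict (see :mod:`seqqc.grids`), an explicit
    list of :class:`ModelSpec`, or None for the shipped default grid.
    Returns candidates ranked by mean CV auROC (ties: lower Brier,
    fewer features, lexicographic spec).  Raises when either class has
    fewer members than ``folds``.
    """
    df = matrix.df if isinstance(matrix, FeatureMatrix) else matrix
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("grid search requires both classes present")
    if counts.min() < folds:
        raise ValueError(f"minority class has {counts.min()} members; needs >= {folds} for stratified CV")
    if grid is None:
        specs = expand_grid(load_grid())
    elif isinstance(grid, dict):
        specs = expand_grid(grid)
    else:
        specs = list(grid)
    if not specs:
        raise ValueError("empty grid")

    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    X = df.to_numpy(float)
    results: list[GridResult] = []
    for spec in specs:
        pipe = _build_pipeline(spec, seed)
        raw = cross_validate(pipe, X, y, cv=cv, scoring=_SCORERS, n_jobs=n_jobs)
        metrics = {}
        for name in _SCORERS:
            vals = raw[f"test_{name}"]
            if name == "brier":
                vals = -vals
            metrics[name] = {"mean": float(np.mean(vals)), "sd": float(np.std(vals))}
        results.append(
            GridResult(
                spec=spec,
                cv_metrics=metrics,
                n_features=_k_of(spec.k_fraction, X.shape[1]),
                folds=folds,
            )
        )
    results.sort(key=lambda r: (-r.auroc, r.brier, r.n_features, r.spec.key()))
    return results


@dataclass
class TunedModel:
    """A fitted pipeline plus everything needed to reproduce and apply it."""

    spec: ModelSpec
    pipeline: Pipeline
    columns: list[str]
    seed: int
    fingerprint: str
    cv_metrics: dict | None = None
    folds: int | None = None

    def save(self, path: str | Path) -> None:
        """Serialize to ``<path>`` (joblib) with a JSON sidecar ``<path>.json``."""
        path = Path(path)
        joblib.dump(self, path)
        sidecar = {
            "spec": self.spec.to_dict(),
            "columns": self.columns,
            "seed": self.seed,
            "fingerprint": self.fingerprint,
            "cv_metrics": self.cv_metrics,
            "folds": self.folds,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @staticmethod
    def load(path: str | Path) -> "TunedModel":
        model = joblib.load(path)
        if not isinstance(model, TunedModel):
            raise TypeError(f"{path} does not contain a TunedModel")
        return model


def train_final(
    matrix: FeatureMatrix | pd.DataFrame,
    labels: Sequence[int],
    spec: ModelSpec,
    seed: int = 0,
    cv_metrics: dict | None = None,
    folds: int | None = None,
) -> TunedModel:
    """Fit ``spec`` on all rows and package it as a :class:`TunedModel`."""
    df = matrix.df if isinstance(matrix, FeatureMatrix) else matrix
    y = np.asarray(labels)
    if len(df) != len(y):
        raise ValueError("matrix and labels length mismatch")
    pipe = _build_pipeline(spec, seed)
    pipe.fit(df.to_numpy(float), y)
    return TunedModel(
        spec=spec,
        pipeline=pipe,
        columns=list(df.columns),
        seed=seed,
        fingerprint=_fingerprint(df, y),
        cv_metrics=cv_metrics,
        folds=folds,
    )


def predict(model: TunedModel, rows: FeatureMatrix | pd.DataFrame) -> pd.DataFrame:
    """Predict ``P_low`` per sample; the row schema must match the model's."""
    df = rows.df if isinstance(rows, FeatureMatrix) else rows
    missing = [c for c in model.columns if c not in df.columns]
    extra = [c for c in df.columns if c not in model.columns]
    if missing or extra:
        raise ValueError(f"feature schema mismatch; missing={missing} extra={extra}")
    X = df[model.columns].to_numpy(float)
    proba = model.pipeline.predict_proba(X)
    low_idx = list(model.pipeline.classes_).index(1)
    return pd.DataFrame({"sample_id": df.index, "P_low": proba[:, low_idx]}).set_index("sample_id")


def brier(probabilities: Sequence[float], labels: Sequence[int]) -> float:
    """Mean squared difference between predicted probability and binary label."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels length mismatch")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((p - y) ** 2))
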