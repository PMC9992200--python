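"""Uniform train/predict contract over the five supervised classifiers.

Families mirror the published setup: two gradient-boosted tree models
(depth-3 trees at learning rate 0.3; 31-leaf leaf-wise trees at learning
rate 0.05), a linear-kernel SVM, Gaussian naive Bayes, and L2 logistic
regression. The tree boosters are backed by scikit-learn's
GradientBoostingClassifier and HistGradientBoostingClassifier behind the
same contract, since the dedicated booster libraries are not part of the
supported runtime.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, HistGradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from cxrnlp.metrics import confusion, metrics

__all__ = ["MODEL_FAMILIES", "ModelSpec", "TrainedModel", "fit", "predict", "benchmark_suite", "default_specs"]

MODEL_FAMILIES = ("xgboost", "lightgbm", "svm_linear", "gaussian_nb", "logistic_regression")

_DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "xgboost": {"max_depth": 3, "learning_rate": 0.3, "n_estimators": 100},
    "lightgbm": {"num_leaves": 31, "learning_rate": 0.05, "n_estimators": 100},
    "svm_linear": {"kernel": "linear", "C": 1.0},
    "gaussian_nb": {},
    "logistic_regression": {"C": 1.0, "max_iter": 1000},  # sklearn default penalty is L2
}


@dataclass(frozen=True)
class ModelSpec:
    family: str
    hyperparameters: dict = dc_field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"family must be one of {MODEL_FAMILIES}, got {self.family!r}")

    def resolved_hyperparameters(self) -> dict:
        params = dict(_DEFAULT_HYPERPARAMETERS[self.family])
        params.update(self.hyperparameters)
        return params


def default_specs(seed: int = 0) -> list[ModelSpec]:
    return [ModelSpec(family=f, seed=seed) for f in MODEL_FAMILIES]


@dataclass
class TrainedModel:
    spec: ModelSpec
    estimator: object
    feature_names: tuple[str, ...]
    training_summary: dict

    def save(self, directory) -> None:
        """Persist spec + feature names as text; estimator via joblib-free
        pickle is deliberately not offered (text-only artifacts)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "spec.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "family": self.spec.family,
                    "hyperparameters": self.spec.resolved_hyperparameters(),
                    "seed": self.spec.seed,
                    "training_summary": self.training_summary,
                },
                fh,
                indent=2,
            )
        (directory / "feature_names.txt").write_text("\n".join(self.feature_names) + "\n", encoding="utf-8")


def _build_estimator(spec: ModelSpec):
    p = spec.resolved_hyperparameters()
    if spec.family == "xgboost":
        return GradientBoostingClassifier(
            max_depth=p["max_depth"],
            learning_rate=p["learning_rate"],
            n_estimators=p["n_estimators"],
            random_state=spec.seed,
        )
    if spec.family == "lightgbm":
        return HistGradientBoostingClassifier(
            max_leaf_nodes=p["num_leaves"],
            learning_rate=p["learning_rate"],
            max_iter=p["n_estimators"],
            early_stopping=False,
            random_state=spec.seed,
        )
    if spec.family == "svm_linear":
        return SVC(kernel=p["kernel"], C=p["C"], random_state=spec.seed)
    if spec.family == "gaussian_nb":
        return GaussianNB()
    if spec.family == "logistic_regression":
        return LogisticRegression(C=p["C"], max_iter=p["max_iter"], random_state=spec.seed)
    raise AssertionError(spec.family)


def _validate_xy(X: np.ndarray, y: Optional[np.ndarray], feature_names: Sequence[str]) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    if X.shape[1] != len(feature_names):
        raise ValueError(f"feature matrix has {X.shape[1]} columns but {len(feature_names)} feature names")
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains missing or non-finite values")
    return X


def fit(X: np.ndarray, y: Sequence[int], spec: ModelSpec, feature_names: Sequence[str]) -> TrainedModel:
    """Train one classifier; deterministic for fixed inputs and seed."""
    feature_names = tuple(feature_names)
    X = _validate_xy(X, None, feature_names)
    y = np.asarray(y, dtype=np.int64)
    if y.shape != (X.shape[0],):
        raise ValueError("labels must be a vector aligned with the feature matrix rows")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 training rows")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(f"training labels must contain both classes 0 and 1, got {classes.tolist()}")
    estimator = _build_estimator(spec)
    estimator.fit(X, y)
    train_acc = float(np.mean(estimator.predict(X) == y))
    summary = {
        "n": int(X.shape[0]),
        "prevalence": float(np.mean(y)),
        "training_accuracy": train_acc,
        **spec.resolved_hyperparameters(),
    }
    return TrainedModel(spec=spec, estimator=estimator, feature_names=feature_names, training_summary=summary)


def predict(model: TrainedModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels and [0, 1] scores monotone in the native decision value.

    The SVM thresholds its signed margin at 0 (score is the
    logistic-squashed margin); all other families threshold the class-1
    probability at 0.5.
    """
    X = _validate_xy(X, None, model.feature_names)
    if model.spec.family == "svm_linear":
        margin = model.estimator.decision_function(X)
        labels = (margin > 0).astype(np.int64)
        scores = 1.0 / (1.0 + np.exp(-margin))
    else:
        scores = model.estimator.predict_proba(X)[:, 1]
        labels = (scores > 0.5).astype(np.int64)
    return labels, scores


def benchmark_suite(
    X_train: np.ndarray,
    y_train: Sequence[int],
    X_eval: np.ndarray,
    reference_labels: dict,
    specs: Sequence[ModelSpec],
    feature_names: Sequence[str],
    train_ids: Optional[Sequence[str]] = None,
    eval_ids: Optional[Sequence[str]] = None,
) -> list[dict]:
    """Fit each spec and score it against every reference standard.

    ``reference_labels`` maps a standard name (e.g. "expert", "code") to
    the evaluation label vector. Returns one flat row per (model,
    standard) with the full diagnostic panel, ready for CSV export.
    """
    if train_ids is not None and eval_ids is not None:
        overlap = set(train_ids) & set(eval_ids)
        if overlap:
            raise ValueError(f"derivation and validation sets overlap on {len(overlap)} ids")
    if not reference_labels:
        raise ValueError("at least one reference standard is required")
    for name, labels in reference_labels.items():
        if len(labels) != np.asarray(X_eval).shape[0]:
            raise ValueError(f"reference standard {name!r} does not align with the evaluation matrix")
    rows = []
    for spec in specs:
        model = fit(X_train, y_train, spec, feature_names)
        pred, _ = predict(model, X_eval)
        for standard, truth in reference_labels.items():
            ms = metrics(confusion(pred, np.asarray(truth, dtype=np.int64)))
            row = {"model": spec.family, "reference_standard": standard, "seed": spec.seed}
            row.update(ms.as_row())
            rows.append(row)
    return rows
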