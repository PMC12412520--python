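"""Viability classification with a small dense network.

A two-hidden-layer feed-forward network (128 and 10 rectified-linear units,
softmax output, categorical cross-entropy, Adam) maps standardized
morphological features to viability classes.  Validation is
leave-one-experiment-out: each fold trains on all but one independent
experiment and tests on the held-out one, so batch effects cannot leak.
Feature standardization is fit on the training fold only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
    roc_curve,
)
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .features import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierSpec",
    "SpheroidClassifier",
    "FoldResult",
    "ClassifierReport",
    "train_classifier",
    "cross_validate_by_experiment",
    "transfer_evaluate",
    "compute_metrics",
]

POSITIVE_CLASS = "high"


@dataclass(frozen=True)
class ClassifierSpec:
    """Architecture and training settings of the dense network."""

    hidden_sizes: tuple[int, int] = (128, 10)
    epochs: int = 150
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0


class SpheroidClassifier:
    """Standardizing scaler + dense softmax network with per-epoch curves.

    Training runs an explicit epoch loop (one ``partial_fit`` pass per epoch
    with minibatch shuffling) so train/test accuracy and loss can be recorded
    at every epoch — the overfitting monitor.
    """

    def __init__(self, spec: ClassifierSpec, feature_columns: list[str]):
        self.spec = spec
        self.feature_columns = list(feature_columns)
        self.scaler = StandardScaler()
        self.net = MLPClassifier(
            hidden_layer_sizes=spec.hidden_sizes,
            activation="relu",
            solver="adam",
            learning_rate_init=spec.learning_rate,
            batch_size=spec.batch_size,
            random_state=spec.seed,
        )
        self.classes_: np.ndarray | None = None
        self.history: dict[str, list[float]] = {
            "train_accuracy": [],
            "test_accuracy": [],
            "loss": [],
        }

    def fit(self, X, y, X_val=None, y_val=None) -> "SpheroidClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data must contain at least two classes")
        self.classes_ = classes
        self.net.set_params(batch_size=min(self.spec.batch_size, len(y)))
        Xs = self.scaler.fit_transform(X)
        Xv = self.scaler.transform(np.asarray(X_val, dtype=float)) if X_val is not None else None
        for _ in range(self.spec.epochs):
            self.net.partial_fit(Xs, y, classes=classes)
            self.history["loss"].append(float(self.net.loss_))
            self.history["train_accuracy"].append(
                float(accuracy_score(y, self.net.predict(Xs)))
            )
            if Xv is not None:
                self.history["test_accuracy"].append(
                    float(accuracy_score(y_val, self.net.predict(Xv)))
                )
        return self

    def _check_matrix(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_columns):
            raise ValueError("feature dimension mismatch")
        return self.scaler.transform(X)

    def predict(self, X) -> np.ndarray:
        return self.net.predict(self._check_matrix(X))

    def predict_proba(self, X) -> np.ndarray:
        return self.net.predict_proba(self._check_matrix(X))

    def predict_table(self, table: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
        """(predicted labels, class probabilities) for a feature table."""
        missing = [c for c in self.feature_columns if c not in table.data.columns]
        if missing:
            raise ValueError(f"table lacks trained features: {missing}")
        X = table.data[self.feature_columns].to_numpy(dtype=float)
        return self.predict(X), self.predict_proba(X)


@dataclass
class FoldResult:
    """Predictions and metrics for one held-out experiment."""

    test_group: str
    spheroid_ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    proba: pd.DataFrame  # columns = class names
    metrics: dict[str, float]
    roc: tuple[np.ndarray, np.ndarray] | None
    history: dict[str, list[float]]


@dataclass
class ClassifierReport:
    """Per-fold results plus aggregate mean/std of each metric."""

    folds: list[FoldResult]
    aggregate: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.aggregate and self.folds:
            keys = self.folds[0].metrics.keys()
            for key in keys:
                vals = [f.metrics[key] for f in self.folds]
                good = [v for v in vals if np.isfinite(v)]
                self.aggregate[f"mean_{key}"] = float(np.mean(good)) if good else float("nan")
                self.aggregate[f"std_{key}"] = float(np.std(good)) if good else float("nan")

    def predictions_frame(self) -> pd.DataFrame:
        rows = []
        for fold in self.folds:
            for sid, yt, yp in zip(fold.spheroid_ids, fold.y_true, fold.y_pred):
                rows.append(
                    {
                        "spheroid_id": sid,
                        "test_group": fold.test_group,
                        "y_true": yt,
                        "y_pred": yp,
                    }
                )
        return pd.DataFrame(rows)


def compute_metrics(y_true, y_pred, proba=None, classes=None) -> dict[str, float]:
    """Accuracy, precision, recall, f1 and (optionally) ROC-AUC.

    Two-class problems use "high" viability as the positive class; with three
    classes the metrics are macro-averaged and AUC is one-vs-rest macro.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size != y_pred.size:
        raise ValueError("length mismatch between truths and predictions")
    if y_true.size == 0:
        raise ValueError("empty inputs")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)
    binary = classes.size == 2
    kwargs = (
        {"pos_label": POSITIVE_CLASS, "average": "binary"}
        if binary and POSITIVE_CLASS in classes
        else {"average": "macro"}
    )
    out = {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "precision": float(precision_score(y_true, y_pred, zero_division=0, **kwargs)),
        "recall": float(recall_score(y_true, y_pred, zero_division=0, **kwargs)),
        "f1": float(f1_score(y_true, y_pred, zero_division=0, **kwargs)),
    }
    if proba is not None:
        proba = np.asarray(proba, dtype=float)
        if np.unique(y_true).size < 2:
            logger.warning("single-class test fold: AUC undefined")
            out["auc"] = float("nan")
        elif binary:
            pos_idx = int(np.where(classes == POSITIVE_CLASS)[0][0]) if POSITIVE_CLASS in classes else 1
            out["auc"] = float(roc_auc_score(y_true == classes[pos_idx], proba[:, pos_idx]))
        else:
            out["auc"] = float(
                roc_auc_score(y_true, proba, multi_class="ovr", average="macro", labels=classes)
            )
    return out


def train_classifier(
    table: FeatureTable, spec: ClassifierSpec, feature_columns: list[str] | None = None
) -> SpheroidClassifier:
    """Fit the network on a complete feature table (no held-out data)."""
    cols = feature_columns or table.feature_columns
    clf = SpheroidClassifier(spec, cols)
    clf.fit(table.data[cols].to_numpy(dtype=float), table.y)
    return clf


def _evaluate_fold(
    clf: SpheroidClassifier,
    test_data: pd.DataFrame,
    test_group: str,
) -> FoldResult:
    X = test_data[clf.feature_columns].to_numpy(dtype=float)
    y_true = test_data["label"].to_numpy()
    y_pred = clf.predict(X)
    proba = clf.predict_proba(X)
    metrics = compute_metrics(y_true, y_pred, proba=proba, classes=clf.classes_)
    roc = None
    if clf.classes_.size == 2 and np.unique(y_true).size == 2:
        pos_idx = int(np.where(clf.classes_ == POSITIVE_CLASS)[0][0])
        fpr, tpr, _ = roc_curve(y_true == POSITIVE_CLASS, proba[:, pos_idx])
        roc = (fpr, tpr)
    return FoldResult(
        test_group=str(test_group),
        spheroid_ids=list(test_data.get("spheroid_id", pd.Series(range(len(test_data))))),
        y_true=y_true,
        y_pred=y_pred,
        proba=pd.DataFrame(proba, columns=list(clf.classes_)),
        metrics=metrics,
        roc=roc,
        history=clf.history,
    )


def cross_validate_by_experiment(
    table: FeatureTable, spec: ClassifierSpec
) -> ClassifierReport:
    """Leave-one-experiment-out cross-validation.

    One fold per experiment: the model trains on the remaining experiments
    and is tested on the held-out one.  Scaler statistics come from the
    training fold only; test rows never touch training.
    """
    groups = pd.unique(table.groups)
    if len(groups) < 2:
        raise ValueError("need at least two experiment groups for cross-validation")
    folds = []
    for group in groups:
        test_mask = table.data[table.group_column] == group
        train_data = table.data[~test_mask]
        test_data = table.data[test_mask]
        clf = SpheroidClassifier(spec, table.feature_columns)
        clf.fit(
            train_data[table.feature_columns].to_numpy(dtype=float),
            train_data["label"].to_numpy(),
            X_val=test_data[table.feature_columns].to_numpy(dtype=float),
            y_val=test_data["label"].to_numpy(),
        )
        folds.append(_evaluate_fold(clf, test_data, group))
    return ClassifierReport(folds)


def transfer_evaluate(clf: SpheroidClassifier, table: FeatureTable) -> ClassifierReport:
    """Evaluate a fitted model on a different dataset without refitting.

    Features are aligned by name; standardization stays the one fit on the
    source dataset.  Missing features raise an error naming them.
    """
    missing = [c for c in clf.feature_columns if c not in table.data.columns]
    if missing:
        raise ValueError(f"target dataset lacks features: {missing}")
    return ClassifierReport([_evaluate_fold(clf, table.data, "transfer")])
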