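"""Tests of the dense-network classifier and leave-one-experiment-out CV."""

import numpy as np
import pandas as pd
import pytest

from spheroscreen.classify import (
    ClassifierSpec,
    SpheroidClassifier,
    compute_metrics,
    cross_validate_by_experiment,
    train_classifier,
    transfer_evaluate,
)
from spheroscreen.features import FeatureTable

SPEC = ClassifierSpec(epochs=60, seed=0)


def _separable_table(n=200, n_groups=3, seed=0, shift=0.0):
    """Two well-separated Gaussian blobs in 2-D, split across experiments."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    x1 = y * 4.0 + rng.normal(0, 0.5, n) + shift
    x2 = -y * 3.0 + rng.normal(0, 0.5, n) + shift
    df = pd.DataFrame(
        {
            "spheroid_id": [f"s{i}" for i in range(n)],
            "experiment_id": [f"exp{i % n_groups + 1}" for i in range(n)],
            "concentration_um": 1.0,
            "f1": x1,
            "f2": x2,
            "label": np.where(y == 1, "high", "low"),
        }
    )
    return FeatureTable(df, ["f1", "f2"])


class TestTrainClassifier:
    def test_separable_data_trains_to_high_accuracy(self):
        # linear separability holds by construction (blob means 4 sigma apart)
        table = _separable_table()
        clf = train_classifier(table, SPEC)
        assert clf.history["train_accuracy"][-1] >= 0.99

    def test_shuffled_labels_no_signal(self):
        rng = np.random.default_rng(5)
        table = _separable_table(seed=5)
        shuffled = table.data.copy()
        shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
        t2 = FeatureTable(shuffled, ["f1", "f2"])
        spec = ClassifierSpec(epochs=40, seed=5)
        report = cross_validate_by_experiment(t2, spec)
        assert abs(report.aggregate["mean_accuracy"] - 0.5) <= 0.12

    def test_same_seed_identical_predictions(self):
        table = _separable_table()
        c1 = train_classifier(table, SPEC)
        c2 = train_classifier(table, SPEC)
        assert np.array_equal(c1.predict_proba(table.X), c2.predict_proba(table.X))

    def test_single_class_raises(self):
        table = _separable_table()
        df = table.data[table.data["label"] == "high"]
        with pytest.raises(ValueError):
            train_classifier(FeatureTable(df, ["f1", "f2"]), SPEC)


class TestCrossValidation:
    def test_one_fold_per_experiment_disjoint(self):
        table = _separable_table(n_groups=3)
        report = cross_validate_by_experiment(table, SPEC)
        assert len(report.folds) == 3
        groups = {f.test_group for f in report.folds}
        assert groups == {"exp1", "exp2", "exp3"}
        all_ids = [sid for f in report.folds for sid in f.spheroid_ids]
        assert len(all_ids) == len(set(all_ids)) == len(table.data)

    def test_single_group_raises(self):
        table = _separable_table(n_groups=1)
        with pytest.raises(ValueError):
            cross_validate_by_experiment(table, SPEC)

    def test_no_leakage_from_test_labels(self):
        table = _separable_table()
        r1 = cross_validate_by_experiment(table, SPEC)
        corrupted = table.data.copy()
        mask = corrupted["experiment_id"] == "exp1"
        corrupted.loc[mask, "label"] = np.where(
            corrupted.loc[mask, "label"] == "high", "low", "high"
        )
        r2 = cross_validate_by_experiment(FeatureTable(corrupted, ["f1", "f2"]), SPEC)
        f1_a = next(f for f in r1.folds if f.test_group == "exp1")
        f1_b = next(f for f in r2.folds if f.test_group == "exp1")
        assert np.array_equal(f1_a.y_pred, f1_b.y_pred)
        assert np.allclose(f1_a.proba.to_numpy(), f1_b.proba.to_numpy())

    def test_f1_is_harmonic_mean_each_fold(self):
        table = _separable_table(seed=2)
        report = cross_validate_by_experiment(table, SPEC)
        for fold in report.folds:
            p, r = fold.metrics["precision"], fold.metrics["recall"]
            if p + r > 0:
                assert fold.metrics["f1"] == pytest.approx(2 * p * r / (p + r))

    def test_training_curves_recorded(self):
        table = _separable_table()
        report = cross_validate_by_experiment(table, SPEC)
        for fold in report.folds:
            assert len(fold.history["train_accuracy"]) == SPEC.epochs
            assert len(fold.history["test_accuracy"]) == SPEC.epochs
            assert len(fold.history["loss"]) == SPEC.epochs


class TestTransfer:
    def test_same_dataset_matches_resubstitution(self):
        table = _separable_table()
        clf = train_classifier(table, SPEC)
        report = transfer_evaluate(clf, table)
        preds = clf.predict(table.X)
        acc = float(np.mean(preds == table.y))
        assert report.folds[0].metrics["accuracy"] == pytest.approx(acc)

    def test_column_order_irrelevant(self):
        table = _separable_table()
        clf = train_classifier(table, SPEC)
        permuted = FeatureTable(
            table.data[["label", "f2", "f1", "experiment_id", "spheroid_id",
                        "concentration_um"]].copy(),
            ["f1", "f2"],
        )
        r1 = transfer_evaluate(clf, table)
        r2 = transfer_evaluate(clf, permuted)
        assert r1.folds[0].metrics == r2.folds[0].metrics

    def test_missing_feature_named_in_error(self):
        table = _separable_table()
        clf = train_classifier(table, SPEC)
        broken = FeatureTable(table.data.drop(columns=["f2"]), ["f1"])
        with pytest.raises(ValueError, match="f2"):
            transfer_evaluate(clf, broken)


class TestThreeClass:
    def test_three_class_training_and_macro_metrics(self):
        rng = np.random.default_rng(9)
        n = 180
        y = rng.integers(0, 3, n)
        x1 = y * 3.0 + rng.normal(0, 0.4, n)
        df = pd.DataFrame(
            {
                "spheroid_id": [f"s{i}" for i in range(n)],
                "experiment_id": [f"exp{i % 2 + 1}" for i in range(n)],
                "concentration_um": 1.0,
                "f1": x1,
                "f2": rng.normal(size=n),
                "label": np.array(["low", "intermediate", "high"])[y],
            }
        )
        table = FeatureTable(df, ["f1", "f2"])
        report = cross_validate_by_experiment(table, ClassifierSpec(epochs=80, seed=1))
        fold = report.folds[0]
        assert fold.proba.shape[1] == 3
        assert report.aggregate["mean_f1"] > 0.8  # macro-averaged
        assert 0 <= report.aggregate["mean_auc"] <= 1


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array(["high", "low", "high"])
        m = compute_metrics(y, y)
        assert all(m[k] == 1.0 for k in ("accuracy", "precision", "recall", "f1"))

    def test_confusion_matrix_hand_example(self):
        truths = np.array(["high", "high", "low", "low"])
        preds = np.array(["high", "low", "low", "low"])
        m = compute_metrics(truths, preds)
        assert m["accuracy"] == pytest.approx(0.75)
        assert m["precision"] == pytest.approx(1.0)
        assert m["recall"] == pytest.approx(0.5)
        assert m["f1"] == pytest.approx(2 / 3)

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(8)
        y = np.where(rng.integers(0, 2, 500) == 1, "high", "low")
        proba = rng.random((500, 2))
        proba /= proba.sum(axis=1, keepdims=True)
        m = compute_metrics(y, np.where(proba[:, 0] > 0.5, "high", "low"),
                            proba=proba, classes=np.array(["high", "low"]))
        assert abs(m["auc"] - 0.5) <= 0.1

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array(["high"]), np.array(["high", "low"]))
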