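"""Confusion-matrix, weighted-metric, audit and ROC tests against
independent brute-force oracles."""

import numpy as np
import pytest

from mbinet.labels import CLASS_NAMES
from mbinet.train import (
    class_metrics,
    confusion_matrix,
    misclassification_audit,
    roc_auc,
)

PAPER_SUPPORTS = (300, 215, 215, 200, 200, 190)


def brute_force_metrics(y_true, y_pred, n_classes=6):
    """Per-sample tally oracle for one-vs-rest metrics, no matrix algebra."""
    out = {}
    total = len(y_true)
    for c in range(n_classes):
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        tn = total - tp - fn - fp
        if tp + fn == 0:
            continue
        out[c] = {
            "accuracy": (tp + tn) / total,
            "recall": tp / (tp + fn),
            "specificity": tn / (fp + tn),
            "precision": tp / (tp + fp) if tp + fp else 0.0,
            "f1": 2 * tp / (2 * tp + fn + fp),
            "support": tp + fn,
        }
    return out


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = np.repeat(np.arange(6), [4, 3, 2, 5, 1, 6])
        cm = confusion_matrix(y, y)
        np.testing.assert_array_equal(cm.counts, np.diag([4, 3, 2, 5, 1, 6]))

    def test_single_predicted_class_single_column(self):
        y = np.repeat(np.arange(6), 3)
        cm = confusion_matrix(y, np.zeros_like(y))
        assert cm.counts[:, 0].sum() == 18
        assert cm.counts[:, 1:].sum() == 0

    def test_matches_pairwise_tally_oracle(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 6, size=50)
        y_pred = rng.integers(0, 6, size=50)
        cm = confusion_matrix(y_true, y_pred)
        for i in range(6):
            for j in range(6):
                expected = sum(
                    1 for t, p in zip(y_true, y_pred) if t == i and p == j
                )
                assert cm.counts[i, j] == expected

    def test_conservation(self):
        rng = np.random.default_rng(1)
        y_true = rng.integers(0, 6, size=123)
        y_pred = rng.integers(0, 6, size=123)
        cm = confusion_matrix(y_true, y_pred)
        assert cm.total == 123
        for c in range(6):
            assert cm.counts[c].sum() == np.sum(y_true == c)

    def test_length_mismatch_and_bad_labels(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 1], [0])
        with pytest.raises(ValueError):
            confusion_matrix([0, 7], [0, 1])


class TestClassMetrics:
    def test_diagonal_matrix_all_ones(self):
        y = np.repeat(np.arange(6), 10)
        report = class_metrics(confusion_matrix(y, y))
        for m in ("accuracy", "precision", "recall", "specificity", "f1"):
            assert report.weighted[m] == pytest.approx(1.0)
        assert report.overall_accuracy == 1.0

    def test_recall_rounding_for_215_support_class(self):
        """A 215-image class with 5 errors has recall 210/215 = 97.674...%,
        printing as 97.67 at two decimals."""
        y_true = np.concatenate([np.full(215, 1), np.full(85, 0)])
        y_pred = y_true.copy()
        y_pred[:5] = 0  # five BT images missed
        report = class_metrics(confusion_matrix(y_true, y_pred))
        assert report.round_percent("recall", "BT") == 97.67

    def test_agrees_with_brute_force_on_200_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(20, 80))
            y_true = rng.integers(0, 6, size=n)
            y_pred = rng.integers(0, 6, size=n)
            report = class_metrics(confusion_matrix(y_true, y_pred))
            oracle = brute_force_metrics(y_true, y_pred)
            for c, vals in oracle.items():
                row = report.per_class.loc[CLASS_NAMES[c]]
                for m, v in vals.items():
                    assert row[m] == pytest.approx(v, abs=1e-12), (c, m)
            # weighted values against the tally oracle
            w = sum(v["support"] for v in oracle.values())
            for m in ("accuracy", "precision", "recall", "specificity", "f1"):
                expected = sum(v[m] * v["support"] for v in oracle.values()) / w
                assert report.weighted[m] == pytest.approx(expected, abs=1e-12)

    def test_weighted_recall_bounded_by_per_class_extremes(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            y_true = rng.integers(0, 6, size=120)
            y_pred = np.where(rng.uniform(size=120) < 0.7, y_true,
                              rng.integers(0, 6, size=120))
            report = class_metrics(confusion_matrix(y_true, y_pred))
            recalls = report.per_class["recall"].dropna()
            assert recalls.min() - 1e-12 <= report.weighted["recall"] <= recalls.max() + 1e-12

    def test_agrees_with_sklearn_weighted_scores(self):
        from sklearn.metrics import precision_recall_fscore_support

        rng = np.random.default_rng(8)
        y_true = rng.integers(0, 6, size=300)
        y_pred = rng.integers(0, 6, size=300)
        report = class_metrics(confusion_matrix(y_true, y_pred))
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, average="weighted", zero_division=0
        )
        assert report.weighted["precision"] == pytest.approx(p, abs=1e-12)
        assert report.weighted["recall"] == pytest.approx(r, abs=1e-12)
        assert report.weighted["f1"] == pytest.approx(f, abs=1e-12)

    def test_zero_support_class_excluded_with_warning(self):
        y_true = np.repeat([0, 1, 2, 3, 4], 10)  # BMT absent
        with pytest.warns(UserWarning, match="BMT"):
            report = class_metrics(confusion_matrix(y_true, y_true))
        assert np.isnan(report.per_class.loc["BMT", "recall"])
        assert report.weighted["recall"] == pytest.approx(1.0)


class TestMisclassificationAudit:
    def test_reference_recall_list_gives_32_errors(self):
        recalls = (100, 97.67, 97.20, 96.00, 96.50, 96.84)
        assert misclassification_audit(recalls, PAPER_SUPPORTS) == 32

    def test_perfect_recalls_give_zero(self):
        assert misclassification_audit([100] * 6, PAPER_SUPPORTS) == 0

    def test_half_recall_hand_arithmetic(self):
        assert misclassification_audit([50] * 6, [10] * 6) == 30

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            misclassification_audit([101, 0, 0, 0, 0, 0], [1] * 6)


class TestRocAuc:
    def test_one_hot_scores_give_auc_one(self):
        y = np.repeat(np.arange(6), 4)
        scores = np.eye(6)[y]
        _, overall = roc_auc(scores, y)
        assert overall == pytest.approx(1.0)

    def test_constant_scores_give_chance_level(self):
        y = np.repeat(np.arange(6), 4)
        scores = np.full((24, 6), 1 / 6)
        _, overall = roc_auc(scores, y)
        assert overall == pytest.approx(0.5)

    def test_two_class_toy_matches_trapezoid_oracle(self):
        """Eight samples, hand-listed scores; AUC by explicit threshold sweep
        plus trapezoidal integration."""
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        s1 = np.array([0.1, 0.4, 0.35, 0.8, 0.7, 0.55, 0.9, 0.65])
        scores = np.stack([1 - s1, s1], axis=1)

        thresholds = np.unique(np.concatenate([[-np.inf, np.inf], s1]))[::-1]
        pts = []
        for th in thresholds:
            pred = s1 >= th
            tpr = np.sum(pred & (y == 1)) / 4
            fpr = np.sum(pred & (y == 0)) / 4
            pts.append((fpr, tpr))
        pts = sorted(set(pts))
        xs = [p[0] for p in pts]
        ys = [p[1] for p in pts]
        expected = np.trapezoid(ys, xs)

        curves, _ = roc_auc(scores, y, average="macro")
        assert curves["BT"][2] == pytest.approx(expected, abs=1e-12)

    def test_absent_class_flagged(self):
        y = np.zeros(10, dtype=int)
        scores = np.random.default_rng(0).uniform(size=(10, 6))
        scores /= scores.sum(axis=1, keepdims=True)
        with pytest.warns(UserWarning):
            curves, _ = roc_auc(scores, y, average="micro")
        assert curves["BT"] is None


class TestFoldAggregation:
    def test_mean_and_sample_std(self):
        # two folds with accuracies 0.9 and 1.0: mean 0.95, sample std ~0.0707
        vals = np.array([0.9, 1.0])
        assert vals.mean() == pytest.approx(0.95)
        assert vals.std(ddof=1) == pytest.approx(0.0707, abs=5e-4)

    def test_summary_shape(self):
        import pandas as pd

        from mbinet.train import CrossValResult, MetricsReport

        def rep(acc):
            frame = pd.DataFrame(
                {m: [acc] for m in ("accuracy", "precision", "recall",
                                    "specificity", "f1")},
                index=["NT"],
            )
            frame["support"] = [10]
            weighted = {m: acc for m in ("accuracy", "precision", "recall",
                                         "specificity", "f1")}
            return MetricsReport(frame, weighted, acc)

        res = CrossValResult([rep(0.9), rep(1.0)], [], [], [], [], None)
        table = res.summary()
        assert table.loc["accuracy", "mean"] == pytest.approx(0.95)
        assert table.loc["accuracy", "std"] == pytest.approx(np.std([0.9, 1.0], ddof=1))
        # identical metrics across folds -> zero dispersion
        res2 = CrossValResult([rep(0.8), rep(0.8)], [], [], [], [], None)
        assert res2.summary()["std"].max() == 0.0
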