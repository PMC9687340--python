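"""Confusion matrices, the four metrics, and the classical baselines."""

import numpy as np
import pytest

from wormstage.evaluation import (
    ConfusionMatrix,
    confusion,
    metrics,
    run_feature_baselines,
)


class TestConfusion:
    def test_perfect_prediction_diagonal(self):
        y = np.array([1, 2, 2, 3, 6, 6, 6])
        cm = confusion(y, y)
        assert np.array_equal(np.diag(cm.counts), np.array([1, 2, 1, 0, 0, 3]))
        assert cm.counts.sum() == len(y)
        assert np.trace(cm.counts) == len(y)

    def test_single_column_when_all_predicted_one(self):
        y = np.array([1, 2, 3, 4, 5, 6])
        cm = confusion(y, np.ones(6, dtype=int))
        assert cm.counts[:, 0].sum() == 6
        assert cm.counts[:, 1:].sum() == 0

    def test_matches_bruteforce_tally(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(1, 7, 200)
        y_pred = rng.integers(1, 7, 200)
        cm = confusion(y_true, y_pred)
        for i in range(1, 7):
            for j in range(1, 7):
                expected = int(np.sum((y_true == i) & (y_pred == j)))
                assert cm.counts[i - 1, j - 1] == expected

    def test_label_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 7], [1, 1])
        with pytest.raises(ValueError):
            confusion([0], [1])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion([], [])


class TestMetrics:
    def test_perfect_classifier_all_ones(self):
        cm = confusion([1, 2, 3, 4, 5, 6] * 3, [1, 2, 3, 4, 5, 6] * 3)
        report = metrics(cm)
        assert report.overall_accuracy == 1.0
        valid = report.per_class.dropna()
        assert np.allclose(valid[["AC", "Recall", "P", "F1"]], 1.0)

    def test_binary_hand_arithmetic(self):
        """cm [[8,2],[3,7]]: class-1 recall 8/10, precision 8/11, F1 from
        the harmonic-mean formula."""
        cm = ConfusionMatrix(counts=np.array([[8, 2], [3, 7]]))
        report = metrics(cm)
        row = report.per_class.iloc[0]
        p, r = 8 / 11, 8 / 10
        assert row["Recall"] == pytest.approx(r)
        assert row["P"] == pytest.approx(p)
        assert row["F1"] == pytest.approx(2 * p * r / (p + r))
        assert row["AC"] == pytest.approx(15 / 20)
        assert report.overall_accuracy == pytest.approx(15 / 20)

    def test_degenerate_precision_recall_zero_f1(self):
        # class 1 never predicted and never correct: P + R = 0 -> F1 = 0
        cm = ConfusionMatrix(counts=np.array([[0, 5], [0, 5]]))
        report = metrics(cm)
        assert report.per_class.iloc[0]["F1"] == 0.0

    def test_zero_support_class_excluded_from_macro(self):
        cm = ConfusionMatrix(counts=np.array([[10, 0, 0], [1, 9, 0], [0, 0, 0]]))
        report = metrics(cm)
        assert np.isnan(report.per_class.iloc[2]["Recall"])
        assert not np.isnan(report.macro["Recall"])

    def test_overall_accuracy_is_trace_over_total(self):
        rng = np.random.default_rng(1)
        y_true = rng.integers(1, 7, 300)
        y_pred = rng.integers(1, 7, 300)
        cm = confusion(y_true, y_pred)
        assert metrics(cm).overall_accuracy == pytest.approx(
            np.trace(cm.counts) / 300
        )

    def test_agreement_with_sklearn_on_random_matrices(self):
        """Independent route: sklearn recall/precision computed from label
        vectors reconstructed off the same confusion matrix."""
        from sklearn.metrics import precision_score, recall_score

        rng = np.random.default_rng(7)
        for _ in range(100):
            k = 4
            counts = rng.integers(0, 12, size=(k, k))
            if counts.sum() == 0 or (counts.sum(axis=1) == 0).any():
                continue
            y_true, y_pred = [], []
            for i in range(k):
                for j in range(k):
                    y_true += [i + 1] * counts[i, j]
                    y_pred += [j + 1] * counts[i, j]
            report = metrics(ConfusionMatrix(counts=counts))
            assert report.macro["Recall"] == pytest.approx(
                recall_score(y_true, y_pred, average="macro", zero_division=0)
            )
            assert report.macro["P"] == pytest.approx(
                precision_score(y_true, y_pred, average="macro", zero_division=0)
            )


class TestFeatureBaselines:
    def test_separable_features_random_forest_accurate(self):
        rng = np.random.default_rng(0)
        labels = np.repeat(np.arange(1, 7), 40)
        features = labels[:, None] * 5.0 + rng.normal(size=(240, 12))
        reports = run_feature_baselines(features, labels, seed=0)
        assert set(reports) == {"random_forest", "svm"}
        assert reports["random_forest"].overall_accuracy >= 0.95

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(3)
        labels = np.repeat(np.arange(1, 7), 50)
        features = labels[:, None] * 5.0 + rng.normal(size=(300, 12))
        shuffled = rng.permutation(labels)
        reports = run_feature_baselines(features, shuffled, seed=3)
        for report in reports.values():
            assert abs(report.overall_accuracy - 1 / 6) <= 0.12

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        labels = np.repeat(np.arange(1, 7), 20)
        features = labels[:, None] + rng.normal(size=(120, 12))
        a = run_feature_baselines(features, labels, seed=5)
        b = run_feature_baselines(features, labels, seed=5)
        for name in a:
            assert a[name].per_class.equals(b[name].per_class)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            run_feature_baselines(np.ones((10, 3)), np.ones(10, dtype=int))
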