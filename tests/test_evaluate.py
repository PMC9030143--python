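"""Cross-validation harness, confusion metrics and ROC/AUC."""

import itertools

import numpy as np
import pytest

from longconn.evaluate import (ConfusionCounts, compute_metrics, kfold_split,
                               roc_auc, run_comparison)
from longconn.model import TrainConfig, CNNConfig, StackConfig


class TestKFold:
    def test_partition_contract(self):
        subjects = [f"s{i}" for i in range(100)]
        labels = [i % 2 for i in range(100)]
        fa = kfold_split(subjects, labels, k=5, seed=3)
        sizes = [len(fa.test_subjects(f)) for f in range(5)]
        assert sizes == [20] * 5
        all_test = [s for f in range(5) for s in fa.test_subjects(f)]
        assert sorted(all_test) == sorted(subjects)

    def test_stratification(self):
        subjects = [f"s{i}" for i in range(100)]
        labels = [i % 2 for i in range(100)]
        fa = kfold_split(subjects, labels, k=5, seed=3)
        lab = dict(zip(subjects, labels))
        for f in range(5):
            pos = sum(lab[s] for s in fa.test_subjects(f))
            assert abs(pos - 10) <= 1

    def test_determinism(self):
        subjects = [f"s{i}" for i in range(30)]
        labels = [i % 2 for i in range(30)]
        assert kfold_split(subjects, labels, seed=8).folds == \
            kfold_split(subjects, labels, seed=8).folds

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="fewer than"):
            kfold_split(["a", "b", "c", "d", "e", "f"], [0, 0, 0, 0, 0, 1], k=5)


class TestMetrics:
    def test_worked_example(self):
        m = compute_metrics(ConfusionCounts(tp=9, tn=8, fp=1, fn=2))
        assert m.accuracy_pct == pytest.approx(85.0)
        assert m.precision_pct == pytest.approx(90.0)
        assert m.recall_pct == pytest.approx(81.8, abs=0.05)

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=10))
        assert (m.accuracy, m.precision, m.recall) == (1.0, 1.0, 1.0)

    def test_exhaustive_small_tables(self):
        """Every confusion table with total <= 6 against direct recomputation."""
        for tp, tn, fp, fn in itertools.product(range(7), repeat=4):
            total = tp + tn + fp + fn
            if total < 1 or total > 6:
                continue
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
            assert m.accuracy == pytest.approx((tp + tn) / total)
            if tp + fp:
                assert m.precision == pytest.approx(tp / (tp + fp))
            else:
                assert m.precision is None
            if tp + fn:
                assert m.recall == pytest.approx(tp / (tp + fn))
            else:
                assert m.recall is None

    def test_scale_free(self):
        a = compute_metrics(ConfusionCounts(3, 2, 1, 1))
        b = compute_metrics(ConfusionCounts(30, 20, 10, 10))
        assert (a.accuracy, a.precision, a.recall) == \
            (b.accuracy, b.precision, b.recall)

    def test_undefined_metrics_warn(self):
        with pytest.warns(UserWarning, match="precision"):
            m = compute_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=2))
        assert m.precision is None


def mann_whitney_auc(scores, labels):
    """Pairwise counting oracle: P(score_pos > score_neg) + 0.5 ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        _, auc = roc_auc([0, 0, 1, 1], [0, 0, 1, 1])
        assert auc == pytest.approx(1.0)

    def test_uninformative_scores(self):
        _, auc = roc_auc([0.3] * 6, [0, 1, 0, 1, 0, 1])
        assert auc == pytest.approx(0.5)

    def test_matches_mann_whitney(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 30))
            scores = np.round(rng.standard_normal(n), 1)  # rounding forces ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        scores = rng.standard_normal(40)
        labels = rng.integers(0, 2, size=40)
        labels[0], labels[1] = 0, 1
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_monotone_roc_points(self, rng):
        pts, _ = roc_auc(rng.standard_normal(30), rng.integers(0, 2, size=30) |
                         np.arange(30) % 2)
        assert np.all(np.diff(pts[:, 0]) >= 0)
        assert np.all(np.diff(pts[:, 1]) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestRunComparison:
    TINY_CNN = CNNConfig(blocks=((4, 3, 1), (6, 3, 1), (8, 3, 1)), feature_dim=5)
    TINY_STACK = StackConfig(hidden_size=4, dropout=0.0)

    def test_table_rows_and_fold_pooling(self, tiny_cohort):
        res = run_comparison(tiny_cohort, task="nc-ad", scope="24m", seed=1,
                             train_config=TrainConfig(epochs=3),
                             cnn_config=self.TINY_CNN, stack_config=self.TINY_STACK)
        assert set(res.table["method"]) == {"svm-linear", "cnn-only", "cnn-lstm"}
        for det in res.details.values():
            assert det.pooled.total == 20  # all subjects tested exactly once

    def test_augmentation_stays_in_training_fold(self, tiny_cohort):
        """Synthetic samples never appear among test predictions."""
        res = run_comparison(tiny_cohort, task="nc-ad", scope="24m", seed=1,
                             methods=("svm-linear",), augment_ratio=0.5,
                             gan_config=__import__("longconn.augment",
                                                   fromlist=["GANConfig"]).GANConfig(
                                 noise_dim=8, generator_widths=(16,),
                                 discriminator_widths=(16,), epochs=5))
        det = res.details[("svm-linear", "24m")]
        assert det.pooled.total == 20  # test folds contain only real subjects

    def test_unknown_method_rejected(self, tiny_cohort):
        with pytest.raises(ValueError, match="unknown method"):
            run_comparison(tiny_cohort, methods=("boosted-stumps",))

    def test_unknown_task_rejected(self, tiny_cohort):
        with pytest.raises(ValueError, match="unknown task"):
            run_comparison(tiny_cohort, task="nc-mci")

    def test_strong_effect_separates_with_svm(self, tiny_cohort):
        res = run_comparison(tiny_cohort, task="nc-ad", scope="24m", seed=1,
                             methods=("svm-linear",))
        assert res.table["accuracy_pct"].iloc[0] >= 90.0
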