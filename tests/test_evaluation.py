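"""Confusion-matrix metrics, ROC/AUC, cross-validation and Tukey HSD."""

import numpy as np
import pytest
from scipy import stats
from sklearn.dummy import DummyClassifier

from fluorocold import evaluation
from fluorocold.evaluation import (
    ConfusionMatrix,
    confusion,
    kfold_cv,
    metrics,
    roc_auc,
    tukey_hsd,
)
from fluorocold.models import TrainedModel
from fluorocold.synthetic_data import SpectralDataset


class TestConfusion:
    def test_hand_counted_example(self):
        cm = confusion([0, 0, 1], [0, 1, 1])
        assert np.array_equal(cm.counts[0], [1, 1, 0])
        assert np.array_equal(cm.counts[1], [0, 1, 0])

    def test_perfect_predictions_are_diagonal(self):
        y = np.repeat([0, 1, 2], 5)
        cm = confusion(y, y)
        assert np.array_equal(cm.counts, np.diag([5, 5, 5]))
        assert np.array_equal(np.diag(cm.normalized()), [100, 100, 100])

    def test_normalized_rows_sum_to_100(self):
        rng = np.random.default_rng(0)
        cm = confusion(rng.integers(0, 3, 500), rng.integers(0, 3, 500))
        assert cm.normalized().sum(axis=1) == pytest.approx(np.full(3, 100.0))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion([], [])


class TestMetrics:
    def test_one_vs_rest_worked_example(self):
        """Class-0 reduction with TP=9, FN=1, TN=8, FP=2.

        Balanced accuracy = ((9/10) + (8/10)) * 0.5 * 100 = 85.0,
        precision = 9/11 * 100 = 81.81..., recall = 90.0.
        """
        cm = ConfusionMatrix(np.array([[9, 1, 0], [2, 8, 0], [0, 0, 0]]))
        rep = metrics(cm)
        assert rep.per_class[0]["accuracy"] == pytest.approx(85.0)
        assert rep.per_class[0]["precision"] == pytest.approx(100 * 9 / 11)
        assert rep.per_class[0]["recall"] == pytest.approx(90.0)

    def test_all_correct_scores_100(self):
        cm = confusion(np.repeat([0, 1, 2], 4), np.repeat([0, 1, 2], 4))
        rep = metrics(cm)
        assert (rep.accuracy, rep.precision, rep.recall, rep.f1) == \
            pytest.approx((100, 100, 100, 100))

    def test_f1_fixed_point_when_precision_equals_recall(self):
        # symmetric confusion: every class has precision == recall
        cm = ConfusionMatrix(np.array([[8, 1, 1], [1, 8, 1], [1, 1, 8]]))
        rep = metrics(cm)
        for c in range(3):
            assert rep.per_class[c]["precision"] == pytest.approx(rep.per_class[c]["recall"])
            assert rep.per_class[c]["f1"] == pytest.approx(rep.per_class[c]["precision"])

    def test_weighted_recall_equals_overall_accuracy_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            y_true = rng.integers(0, 3, 300)
            y_pred = rng.integers(0, 3, 300)
            rep = metrics(confusion(y_true, y_pred))
            assert rep.recall == pytest.approx(100 * (y_true == y_pred).mean())

    def test_sample_order_permutation_invariance(self):
        rng = np.random.default_rng(2)
        y_true, y_pred = rng.integers(0, 3, 200), rng.integers(0, 3, 200)
        perm = rng.permutation(200)
        a = metrics(confusion(y_true, y_pred))
        b = metrics(confusion(y_true[perm], y_pred[perm]))
        assert a == b

    def test_zero_predicted_positives_warns_and_scores_zero(self):
        cm = ConfusionMatrix(np.array([[0, 5, 0], [0, 5, 0], [0, 5, 0]]))
        with pytest.warns(UserWarning, match="precision"):
            rep = metrics(cm)
        assert rep.per_class[0]["precision"] == 0.0

    def test_agreement_with_sklearn_weighted_scores(self):
        """Independent cross-check of precision/recall/f1 aggregation."""
        from sklearn.metrics import precision_recall_fscore_support

        rng = np.random.default_rng(3)
        y_true, y_pred = rng.integers(0, 3, 400), rng.integers(0, 3, 400)
        rep = metrics(confusion(y_true, y_pred))
        p, r, f, _ = precision_recall_fscore_support(y_true, y_pred, average="weighted")
        assert rep.precision == pytest.approx(100 * p)
        assert rep.recall == pytest.approx(100 * r)
        assert rep.f1 == pytest.approx(100 * f)


class TestRocAuc:
    def test_perfectly_ordered_scores_give_auc_one(self):
        y = np.repeat([0, 1, 2], 10)
        probs = np.full((30, 3), 0.05)
        probs[np.arange(30), y] = 0.9
        out = roc_auc(y, probs)
        assert all(v == pytest.approx(1.0) for v in out.values())

    def test_truth_independent_scores_sit_at_half(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 3, 5000)
        raw = rng.uniform(size=(5000, 3))
        probs = raw / raw.sum(axis=1, keepdims=True)
        out = roc_auc(y, probs)
        for v in out.values():
            assert v == pytest.approx(0.5, abs=0.03)

    def test_small_case_matches_pairwise_concordance_count(self):
        """AUC equals the Mann-Whitney concordance fraction over 4x4 pairs."""
        pos_scores = [0.9, 0.7, 0.6, 0.2]
        neg_scores = [0.8, 0.5, 0.3, 0.1]
        y = np.array([0] * 4 + [1] * 4)  # class 0 = positives here
        p0 = np.array(pos_scores + neg_scores)
        probs = np.stack([p0, (1 - p0) / 2, (1 - p0) / 2], axis=1)
        concordance = sum(
            1.0 if p > n else 0.5 if p == n else 0.0
            for p in pos_scores for n in neg_scores
        ) / 16
        assert roc_auc(y, probs)[0] == pytest.approx(concordance)

    def test_absent_class_reports_none(self):
        y = np.array([0, 0, 1, 1])
        probs = np.full((4, 3), 1 / 3)
        assert roc_auc(y, probs)[2] is None


def _dummy_factory(ds):
    est = DummyClassifier(strategy="most_frequent").fit(ds.X, ds.y)
    return TrainedModel(kind="lda", estimator=est, label_order=est.classes_,
                        n_bands=ds.X.shape[1])


class TestKfoldCv:
    def test_majority_classifier_recall_equals_prevalence(self):
        """Weighted recall of an always-majority predictor is the majority share.

        Class counts 40/30/30 split into 10 stratified folds of 4/3/3, so
        every fold's weighted recall is exactly 40%.
        """
        rng = np.random.default_rng(5)
        ds = SpectralDataset(rng.normal(size=(100, 25)), np.repeat([0, 1, 2], [40, 30, 30]))
        res = kfold_cv(_dummy_factory, ds, k=10, seed=0)
        mean, sd = res.summary()["recall"]
        assert mean == pytest.approx(40.0)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_folds_partition_the_dataset(self):
        rng = np.random.default_rng(6)
        ds = SpectralDataset(rng.normal(size=(9, 25)), np.repeat([0, 1, 2], 3))
        res = kfold_cv(_dummy_factory, ds, k=3, seed=0)
        supports = sum(sum(r.per_class[c]["support"] for c in range(3)) for r in res.per_fold)
        assert supports == 9 and len(res.per_fold) == 3

    def test_class_smaller_than_k_rejected(self):
        rng = np.random.default_rng(7)
        ds = SpectralDataset(rng.normal(size=(9, 25)), np.repeat([0, 1, 2], 3))
        with pytest.raises(ValueError, match="class"):
            kfold_cv(_dummy_factory, ds, k=5)

    def test_deterministic_model_cv_mean_stable_across_fold_seeds(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(c, 1.0, size=(40, 25)) for c in (0.0, 3.0, 6.0)])
        ds = SpectralDataset(np.clip(X, 0, None), np.repeat([0, 1, 2], 40))

        def factory(sub):
            from fluorocold.models import train_classical
            return train_classical("lda", sub)

        a = kfold_cv(factory, ds, k=5, seed=1).summary()["accuracy"]
        b = kfold_cv(factory, ds, k=5, seed=2).summary()["accuracy"]
        assert abs(a[0] - b[0]) <= max(a[1], b[1]) + 1e-9


class TestTukeyHsd:
    def test_identical_groups_reject_nothing(self):
        g = np.array([85.0, 86.0, 84.5, 85.5, 86.5])
        table = tukey_hsd({"a": g, "b": g.copy(), "c": g.copy()})
        assert not table["reject"].any()

    def test_overwhelming_separation_rejected(self):
        rng = np.random.default_rng(9)
        table = tukey_hsd({
            "low": rng.normal(0, 0.1, 10),
            "high": rng.normal(10, 0.1, 10),
        })
        assert table["reject"].all()

    def test_pvalue_matches_studentized_range_arithmetic(self):
        """3-group case vs direct between/within mean-square computation."""
        groups = {
            "a": np.array([81.0, 83.0, 85.0, 84.0]),
            "b": np.array([86.0, 88.0, 87.0, 89.0]),
            "c": np.array([84.0, 85.0, 86.0, 87.0]),
        }
        table = tukey_hsd(groups)
        arrays = list(groups.values())
        n, k = 4, 3
        mse = sum(a.var(ddof=1) * (n - 1) for a in arrays) / (k * (n - 1))
        se = np.sqrt(mse / n)
        for _, row in table.iterrows():
            i, j = row["group1"], row["group2"]
            q = abs(groups[i].mean() - groups[j].mean()) / se
            expected_p = stats.studentized_range.sf(q, k, k * (n - 1))
            assert row["pvalue"] == pytest.approx(expected_p, abs=1e-6)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError, match="2 values"):
            tukey_hsd({"a": np.array([1.0]), "b": np.array([1.0, 2.0])})
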