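"""Classifier behaviour, confusion statistics, and cross-validation protocol."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from emgpr import FeatureColumn, FeatureMatrix
from emgpr.benchmarks import benchmark_matrices
from emgpr.classify import (
    ClassifierConfig,
    ConfusionMatrix,
    GaussianMLE,
    classwise_accuracy,
    cross_validate,
    mean_recall,
    predict,
    train,
)

SMALL_SVM = ClassifierConfig(svm_c_grid=(1.0, 100.0), svm_gamma_grid=(0.01, 1.0))


def make_fm(X, y):
    cols = tuple(FeatureColumn("X", "value", f"c{i}") for i in range(X.shape[1]))
    return FeatureMatrix(X, cols, np.asarray(y, dtype=object))


def gaussian_blobs(means, n, seed, scale=1.0):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for label, mu in means.items():
        X.append(rng.normal(size=(n, len(mu))) * scale + mu)
        y += [label] * n
    return np.vstack(X), np.array(y, dtype=object)


class TestConfusionStatistics:
    def test_perfect_binary_matrix(self):
        cm = ConfusionMatrix(("a", "b"), counts=np.array([[1, 0], [0, 1]]))
        assert classwise_accuracy(cm) == 100.0
        assert mean_recall(cm) == 100.0

    def test_tp_tn_fp_fn_arithmetic(self):
        # per class: TP=50, TN=40, FP=5, FN=5 -> 90%
        cm = ConfusionMatrix(("a", "b"), counts=np.array([[50, 5], [5, 40]]))
        assert classwise_accuracy(cm) == pytest.approx(90.0)

    def test_all_wrong_binary_matrix(self):
        cm = ConfusionMatrix(("a", "b"), counts=np.array([[0, 1], [1, 0]]))
        assert classwise_accuracy(cm) == 0.0
        assert mean_recall(cm) == 0.0

    def test_identity_percent_matrix(self):
        cm = ConfusionMatrix.from_percent(np.eye(11) * 100.0, [f"c{i}" for i in range(11)])
        assert mean_recall(cm) == 100.0

    def test_row_sums_and_percent_normalisation(self):
        y_true = ["a"] * 5 + ["b"] * 3
        y_pred = ["a", "a", "b", "a", "b", "b", "a", "b"]
        cm = ConfusionMatrix.from_predictions(y_true, y_pred)
        assert cm.counts.sum(axis=1).tolist() == [5, 3]
        np.testing.assert_allclose(cm.percent().sum(axis=1), [100.0, 100.0], atol=1e-9)

    def test_benchmark_diagonal_means(self):
        """The printed averages of the three reference performance matrices."""
        bm = benchmark_matrices()
        assert mean_recall(bm["FS_MLE"]) == pytest.approx(97.43, abs=0.005)
        assert mean_recall(bm["FE_KNN"]) == pytest.approx(90.0, abs=0.05)
        assert mean_recall(bm["LOGRMS_MLP"]) == pytest.approx(95.47, abs=0.005)

    def test_empty_class_excluded_with_warning(self, caplog):
        counts = np.array([[3, 0, 0], [0, 2, 0], [0, 0, 0]])
        cm = ConfusionMatrix(("a", "b", "c"), counts=counts)
        with caplog.at_level("WARNING"):
            assert mean_recall(cm) == pytest.approx(100.0)
        assert "no test windows" in caplog.text


class TestClassifiers:
    def test_mle_on_well_separated_gaussians(self):
        X, y = gaussian_blobs({"lo": [0.0], "hi": [10.0]}, n=200, seed=7)
        Xt, yt = gaussian_blobs({"lo": [0.0], "hi": [10.0]}, n=200, seed=8)
        model = train("mle", make_fm(X, y), seed=7)
        pred = predict(model, make_fm(Xt, yt))
        assert np.mean(pred == yt) >= 0.99

    def test_lda_and_svm_separable_blobs(self):
        means = {"a": [0.0, 0.0], "b": [8.0, 8.0]}
        X, y = gaussian_blobs(means, n=50, seed=1, scale=0.5)
        fm = make_fm(X, y)
        for kind in ("lda", "svm"):
            model = train(kind, fm, config=SMALL_SVM, seed=1)
            assert np.mean(predict(model, fm) == y) == 1.0

    def test_knn_self_prediction_with_distinct_points(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 3))
        y = np.array(["a", "b", "c"] * 20, dtype=object)
        fm = make_fm(X, y)
        model = train("knn", fm, seed=2)
        # every point's nearest neighbour is itself (distance 0 dominates)
        assert np.mean(predict(model, fm) == y) == 1.0

    def test_dt_memorises_distinct_training_rows(self):
        rng = np.random.default_rng(3)
        fm = make_fm(rng.normal(size=(40, 4)), np.array(["a", "b"] * 20, dtype=object))
        model = train("dt", fm, seed=3)
        assert np.mean(predict(model, fm) == fm.labels) == 1.0

    def test_single_class_training_predicts_that_class(self):
        rng = np.random.default_rng(4)
        fm = make_fm(rng.normal(size=(10, 2)), np.array(["only"] * 10, dtype=object))
        model = train("mle", fm, seed=4)
        assert set(predict(model, fm)) == {"only"}

    def test_mle_matches_gaussian_density_oracle(self):
        X, y = gaussian_blobs({"a": [0, 0], "b": [3, 1], "c": [-2, 4]}, n=60, seed=5)
        mle = GaussianMLE().fit(X, y)
        Xt, _ = gaussian_blobs({"a": [0, 0], "b": [3, 1], "c": [-2, 4]}, n=20, seed=6)
        oracle = []
        for row in Xt:
            lls = []
            for cls in mle.classes_:
                Xc = X[y == cls]
                mu = Xc.mean(axis=0)
                cov = np.cov(Xc.T, bias=True)
                lls.append(multivariate_normal(mu, cov).logpdf(row))
            oracle.append(mle.classes_[int(np.argmax(lls))])
        np.testing.assert_array_equal(mle.predict(Xt), np.array(oracle))

    def test_mle_singular_covariance_gets_ridge(self, caplog):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0], [5.0, 1.0], [6.0, 2.0], [7.0, 0.0]])
        y = np.array(["flat", "flat", "flat", "ok", "ok", "ok"])
        with caplog.at_level("WARNING"):
            GaussianMLE().fit(X, y)
        assert "ridge" in caplog.text

    def test_column_layout_mismatch_rejected(self):
        rng = np.random.default_rng(8)
        fm = make_fm(rng.normal(size=(20, 3)), np.array(["a", "b"] * 10, dtype=object))
        model = train("lda", fm, seed=0)
        other = FeatureMatrix(
            fm.values[:, :2],
            tuple(FeatureColumn("Y", "value", f"c{i}") for i in range(2)),
            fm.labels,
        )
        with pytest.raises(ValueError):
            predict(model, other)

    def test_unknown_kind_rejected(self):
        fm = make_fm(np.zeros((4, 2)), np.array(["a", "a", "b", "b"], dtype=object))
        with pytest.raises(ValueError):
            train("forest", fm)


class TestCrossValidation:
    def test_deterministic_given_seed(self, fs_features):
        r1 = cross_validate(fs_features, "mle", folds=10, seed=11)
        r2 = cross_validate(fs_features, "mle", folds=10, seed=11)
        assert r1.mean_accuracy == r2.mean_accuracy
        assert r1.mean_recall == r2.mean_recall
        np.testing.assert_array_equal(r1.confusion.counts, r2.confusion.counts)

    def test_duplicated_subject_gives_identical_accuracies(self, fs_features):
        rep = cross_validate({"s1": fs_features, "s2": fs_features}, "mle", folds=5, seed=0)
        accs = list(rep.per_subject_accuracy.values())
        assert accs[0] == accs[1]
        assert rep.std_accuracy == 0.0

    def test_confusion_row_sums_equal_test_counts(self, fs_features):
        rep = cross_validate(fs_features, "lda", folds=5, seed=3)
        _, counts = np.unique(fs_features.labels.astype(str), return_counts=True)
        np.testing.assert_array_equal(rep.confusion.counts.sum(axis=1), counts)

    def test_timing_fields_recorded(self, fs_features):
        rep = cross_validate(fs_features, "lda", folds=5, seed=3)
        assert rep.train_time > 0.0 and rep.test_time > 0.0

    def test_summary_mentions_key_statistics(self, fs_features):
        rep = cross_validate(fs_features, "mle", folds=5, seed=1)
        text = rep.summary()
        assert "MLE" in text and "recall" in text and "Performance matrix" in text
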