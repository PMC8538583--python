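"""Fold construction, 1-NN CV prediction and evaluation metrics."""

import numpy as np
import pytest

from angioprint.classify_eval import (
    CVConfig,
    compute_metrics,
    knn_cv_predict,
    make_folds,
)


class TestFolds:
    def test_balanced_two_class_ten_fold(self):
        labels = np.repeat(["a", "b"], 10)
        folds = make_folds(labels, CVConfig(seed=0))
        for f in range(10):
            fold_labels = labels[folds == f]
            assert sorted(fold_labels) == ["a", "b"]

    def test_deterministic_given_seed(self):
        labels = np.repeat(np.arange(5), 12)
        f1 = make_folds(labels, CVConfig(seed=3))
        f2 = make_folds(labels, CVConfig(seed=3))
        np.testing.assert_array_equal(f1, f2)

    def test_fold_sizes_for_2156_samples(self):
        # 51 subjects with the real database's total count: fold sizes
        # must be 215 or 216 by pigeonhole
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 51, size=2156)
        while np.bincount(labels, minlength=51).min() < 10:
            labels = rng.integers(0, 51, size=2156)
        folds = make_folds(labels, CVConfig(seed=1))
        sizes = np.bincount(folds, minlength=10)
        assert set(sizes) <= {215, 216}
        # stratification: per-class counts differ by at most one
        for c in range(51):
            per_fold = np.bincount(folds[labels == c], minlength=10)
            assert per_fold.max() - per_fold.min() <= 1

    def test_small_class_error_names_the_class(self):
        labels = np.array(["big"] * 20 + ["tiny"] * 3)
        with pytest.raises(ValueError, match="tiny"):
            make_folds(labels, CVConfig())


class TestKnnCV:
    def test_separated_clouds_are_perfectly_identified(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        y = np.repeat([0, 1], 20)
        X[y == 1] += 10.0  # ten standard deviations apart
        pred, folds = knn_cv_predict(X, y, CVConfig(seed=0))
        assert (pred == y).all()
        assert len(pred) == 40

    def test_duplicated_columns_leave_predictions_unchanged(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 4))
        y = np.tile([0, 1, 2], 10)
        p1, _ = knn_cv_predict(X, y, CVConfig(seed=2))
        p2, _ = knn_cv_predict(np.hstack([X, X]), y, CVConfig(seed=2))
        np.testing.assert_array_equal(p1, p2)

    def test_matches_brute_force_all_pairs_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 5))
        y = np.tile([0, 1, 2], 10)
        cfg = CVConfig(seed=4)
        pred, folds = knn_cv_predict(X, y, cfg)
        # oracle: per fold, standardize by training stats and scan all
        # pairs with explicit loops
        for f in range(cfg.n_folds):
            test_idx = np.flatnonzero(folds == f)
            train_idx = np.flatnonzero(folds != f)
            mu = X[train_idx].mean(axis=0)
            sd = X[train_idx].std(axis=0)
            sd[sd == 0] = 1.0
            for i in test_idx:
                best, best_d = None, np.inf
                for j in train_idx:
                    d = np.sqrt(np.sum(((X[i] - mu) / sd - (X[j] - mu) / sd) ** 2))
                    if d < best_d:
                        best, best_d = j, d
                assert pred[i] == y[best]

    def test_non_finite_features_rejected(self):
        X = np.zeros((20, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            knn_cv_predict(X, np.tile([0, 1], 10), CVConfig())

    def test_zero_variance_column_passes_through(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 3))
        X[:, 2] = 5.0
        y = np.tile([0, 1], 10)
        pred, _ = knn_cv_predict(X, y, CVConfig(seed=0))
        assert len(pred) == 20  # no division error, all samples predicted


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.tile([0, 1, 2], 5)
        rep = compute_metrics(y, y)
        assert rep.accuracy == 100.0
        assert rep.macro_precision == 100.0
        assert rep.macro_recall == 100.0
        assert rep.macro_f1 == 100.0
        assert rep.n_misclassified == 0

    def test_three_errors_among_2156_gives_99_86(self):
        rng = np.random.default_rng(0)
        y_true = np.repeat(np.arange(51), 43)[:2156]
        y_pred = y_true.copy()
        flip = rng.choice(2156, size=3, replace=False)
        y_pred[flip] = (y_true[flip] + 1) % 51
        rep = compute_metrics(y_true, y_pred)
        assert rep.n_misclassified == 3
        assert round(rep.accuracy, 2) == 99.86
        assert rep.rounded()["accuracy"] == 99.86

    def test_hand_built_three_class_confusion(self):
        # true: a a a b b c ; pred: a b a b c c
        y_true = np.array(list("aaabbc"))
        y_pred = np.array(list("abab cc".replace(" ", "")))
        rep = compute_metrics(y_true, y_pred)
        np.testing.assert_array_equal(
            rep.confusion, [[2, 1, 0], [0, 1, 1], [0, 0, 1]]
        )
        # by hand: precision a=2/2, b=1/2, c=1/2; recall a=2/3, b=1/2, c=1/1
        assert rep.macro_precision == pytest.approx(100 * (1 + 0.5 + 0.5) / 3)
        assert rep.macro_recall == pytest.approx(100 * (2 / 3 + 0.5 + 1.0) / 3)
        assert rep.per_subject_recall["a"] == pytest.approx(100 * 2 / 3)

    def test_micro_metrics_equal_accuracy(self):
        rng = np.random.default_rng(1)
        y_true = rng.integers(0, 4, 50)
        y_pred = rng.integers(0, 4, 50)
        rep = compute_metrics(y_true, y_pred)
        assert rep.micro_precision == rep.accuracy
        assert rep.micro_recall == rep.accuracy
        assert rep.micro_f1 == rep.accuracy

    def test_confusion_sums_and_misclassified(self):
        y_true = np.array([0, 0, 1, 1, 2])
        y_pred = np.array([0, 1, 1, 1, 0])
        rep = compute_metrics(y_true, y_pred)
        assert rep.confusion.sum() == 5
        assert rep.n_misclassified == 5 - np.trace(rep.confusion)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.zeros(3), np.zeros(4))

    def test_report_serialization(self, tmp_path):
        y = np.tile([0, 1], 10)
        rep = compute_metrics(y, y)
        rep.save(tmp_path)
        assert (tmp_path / "report.json").exists()
        assert (tmp_path / "confusion_matrix.csv").exists()
        assert (tmp_path / "per_subject_recall.csv").exists()


class TestRunPipeline:
    def test_shapes_and_byte_identical_reports(self, tmp_path):
        from angioprint.classify_eval import run_pipeline
        from angioprint.config import PipelineConfig
        from angioprint.synthetic_angio import SyntheticSpec, generate_dataset

        spec = SyntheticSpec(
            n_subjects=4, frames_per_subject=10, image_size=96, master_seed=3
        )
        ds = generate_dataset(spec)
        cfg = PipelineConfig(nca_epochs=3)
        r1 = run_pipeline(ds, cfg, out_dir=tmp_path / "a")
        r2 = run_pipeline(ds, cfg, out_dir=tmp_path / "b")
        assert r1.confusion.shape == (4, 4)
        assert len(r1.pooled_predictions) == 40
        assert (tmp_path / "a" / "report.json").read_bytes() == (
            tmp_path / "b" / "report.json"
        ).read_bytes()


class TestResubstitution:
    def test_self_excluded_resubstitution_matches_label_of_nearest_other(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(25, 4))
        y = np.tile([0, 1, 2, 3, 4], 5)
        # 1-NN with self excluded: predict label of nearest other point
        from scipy.spatial.distance import cdist

        d = cdist(X, X)
        np.fill_diagonal(d, np.inf)
        pred = y[d.argmin(axis=1)]
        # brute-force oracle
        for i in range(25):
            best, best_d = None, np.inf
            for j in range(25):
                if j == i:
                    continue
                dij = np.sqrt(((X[i] - X[j]) ** 2).sum())
                if dij < best_d:
                    best, best_d = j, dij
            assert pred[i] == y[best]
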