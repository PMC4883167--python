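import itertools

import numpy as np
import pytest

from eegtexture.classify import (
    PRESETS,
    ClassifierConfig,
    chi2_feature_map,
    evaluate_cv,
    intersection_kernel,
    metrics_from_counts,
    train_classifier,
)
from eegtexture.errors import ParameterError, TrainingError
from oracles import chi2_kernel_brute


def probe_grid():
    grid = np.linspace(0.1, 1.0, 4)
    return np.array(list(itertools.product(grid, repeat=4)))


class TestChi2Map:
    def test_zero_maps_to_zero(self):
        mapped = chi2_feature_map(np.zeros(5), order=2)
        assert np.all(mapped == 0)
        other = chi2_feature_map(np.ones(5), order=2)
        assert float(mapped @ other) == 0.0

    def test_output_length(self):
        assert chi2_feature_map(np.ones(4), order=1).shape == (12,)  # 2n+1 = 3 per dim
        assert chi2_feature_map(np.ones(4), order=3).shape == (28,)

    def test_diagonal_error_within_5_percent(self):
        pts = probe_grid()
        mapped = chi2_feature_map(pts, order=1)
        for x, m in zip(pts, mapped):
            exact = chi2_kernel_brute(x, x)
            assert abs(float(m @ m) - exact) / exact <= 0.05

    def test_error_non_increasing_with_order(self):
        pts = probe_grid()[::8]
        errs = []
        for order in (1, 2, 3):
            mapped = chi2_feature_map(pts, order=order)
            worst = max(
                abs(float(mi @ mj) - chi2_kernel_brute(xi, xj)) / chi2_kernel_brute(xi, xj)
                for (xi, mi), (xj, mj) in itertools.product(zip(pts, mapped), repeat=2)
            )
            errs.append(worst)
        assert errs[0] >= errs[1] >= errs[2]

    def test_matches_sklearn_sampler_gram(self):
        """Independent cross-check: identical Gram matrix to scikit-learn's
        additive chi2 sampler at the same order and period."""
        from sklearn.kernel_approximation import AdditiveChi2Sampler

        pts = probe_grid()[::5]
        mine = chi2_feature_map(pts, order=1, period=0.65)
        ref = AdditiveChi2Sampler(sample_steps=2, sample_interval=0.65).fit_transform(pts)
        np.testing.assert_allclose(mine @ mine.T, ref @ ref.T, atol=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ParameterError):
            chi2_feature_map(np.array([0.5, -0.1]))


def toy_separable(n=40, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 0.3, (n // 2, 2)), rng.normal(4, 0.3, (n // 2, 2))])
    y = np.array(["normal"] * (n // 2) + ["seizure"] * (n // 2))
    return X, y


class TestTraining:
    @pytest.mark.parametrize(
        "config",
        [
            ClassifierConfig(solver="kernel-svm", kernel="linear", C=100.0),
            ClassifierConfig(solver="kernel-svm", kernel="polynomial", C=1.0),
            ClassifierConfig(solver="kernel-svm", kernel="intersection", C=1.0),
            ClassifierConfig(solver="linear-primal", penalty="l2", C=1.0),
            ClassifierConfig(solver="linear-primal", penalty="l1", C=1.0),
            ClassifierConfig(solver="linear-primal", penalty="l2", C=1.0,
                             homogeneous_map=(1, None)),
        ],
        ids=["linear", "poly", "intersection", "ll-l2", "ll-l1", "hm-ll"],
    )
    def test_separable_training_accuracy(self, config):
        X, y = toy_separable()
        model = train_classifier(X, y, config)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_deterministic_predictions(self):
        X, y = toy_separable(seed=3)
        cfg = ClassifierConfig(solver="linear-primal", C=1.0, seed=11)
        p1 = train_classifier(X, y, cfg).predict(X)
        p2 = train_classifier(X, y, cfg).predict(X)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(TrainingError):
            train_classifier(X, np.array(["normal"] * 10), ClassifierConfig())

    def test_intersection_kernel_values(self):
        X = np.array([[1.0, 3.0], [2.0, 0.5]])
        K = intersection_kernel(X, X)
        assert K[0, 1] == K[1, 0] == 1.0 + 0.5
        assert K[0, 0] == 4.0


class TestMetrics:
    def test_published_confusion_example(self):
        """TP=95, FN=5, TN=90, FP=10 give 95/90/92.5 percent."""
        m = metrics_from_counts(tp=95, fn=5, tn=90, fp=10)
        assert m["sensitivity"] == pytest.approx(95.0)
        assert m["specificity"] == pytest.approx(90.0)
        assert m["accuracy"] == pytest.approx(92.5)

    def test_perfect_predictions(self):
        m = metrics_from_counts(tp=50, fn=0, tn=50, fp=0)
        assert (m["sensitivity"], m["specificity"], m["accuracy"]) == (100.0, 100.0, 100.0)

    def test_all_positive_predictor_on_balanced_data(self):
        m = metrics_from_counts(tp=50, fn=0, tn=0, fp=50)
        assert m["sensitivity"] == 100.0
        assert m["specificity"] == 0.0
        assert m["accuracy"] == 50.0


class TestCrossValidation:
    def test_report_consistency_and_stratification(self):
        X, y = toy_separable(n=60, seed=5)
        report = evaluate_cv(X, y, ClassifierConfig(C=1.0), k=5, seed=7)
        assert report.tp + report.fn == 30  # all positives accounted for
        assert report.tn + report.fp == 30
        for fold in report.folds:
            pos = fold["tp"] + fold["fn"]
            neg = fold["tn"] + fold["fp"]
            assert abs(pos - neg) <= 1  # stratified folds
        assert 0 <= report.accuracy <= 100

    def test_pooled_accuracy_between_sensitivity_and_specificity(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 4))
        X[30:, 0] += 1.0  # weak signal -> imperfect classifier
        y = np.array(["normal"] * 30 + ["seizure"] * 30)
        r = evaluate_cv(X, y, ClassifierConfig(C=1.0), k=5, seed=1)
        lo, hi = sorted((r.sensitivity, r.specificity))
        assert lo <= r.accuracy <= hi

    def test_fold_error_when_class_too_small(self):
        X = np.random.default_rng(0).normal(size=(8, 2))
        y = np.array(["seizure"] * 3 + ["normal"] * 5)
        with pytest.raises(TrainingError):
            evaluate_cv(X, y, ClassifierConfig(), k=5, seed=0)

    def test_seed_changes_fold_assignment_not_validity(self):
        X, y = toy_separable(n=50, seed=9)
        r1 = evaluate_cv(X, y, ClassifierConfig(C=1.0), k=5, seed=1)
        r2 = evaluate_cv(X, y, ClassifierConfig(C=1.0), k=5, seed=1)
        assert r1.to_dict() == r2.to_dict()


def test_invalid_config_rejected():
    with pytest.raises(ParameterError):
        ClassifierConfig(C=-1.0)
    with pytest.raises(ParameterError):
        ClassifierConfig(solver="forest")
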