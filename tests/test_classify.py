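"""Standardization, correlation-matrix PCA, RBF-SVM and repeated CV."""

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA as SkPCA

from calculoscope import (
    ConfusionCounts,
    confusion_metrics,
    generate_feature_dataset,
    pca_fit,
    pca_transform,
    repeated_kfold_cv,
    standardize,
    summarize_runs,
    svm_predict,
    svm_train,
)
from calculoscope.classify import apply_standardization


class TestStandardize:
    def test_population_zscore_closed_form(self):
        Z, _ = standardize(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(Z.ravel(), [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_columns_are_centered_unit_sd(self, rng):
        Z, _ = standardize(rng.uniform(0, 50, size=(40, 6)))
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-9)

    def test_idempotence(self, rng):
        Z, _ = standardize(rng.normal(size=(30, 4)))
        Z2, _ = standardize(Z)
        np.testing.assert_allclose(Z2, Z, atol=1e-9)

    def test_constant_column_dropped_with_warning(self):
        X = np.column_stack([np.arange(10.0), np.full(10, 7.0)])
        with pytest.warns(UserWarning, match="constant"):
            Z, params = standardize(X)
        assert Z.shape == (10, 1)
        assert list(params.kept) == [True, False]
        # held-out transform respects the dropped column
        assert apply_standardization(params, X[:3]).shape == (3, 1)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            standardize(np.empty((0, 3)))


class TestPCA:
    def test_perfectly_correlated_pair_needs_one_component(self, rng):
        x = rng.normal(size=50)
        Z, _ = standardize(np.column_stack([x, 2 * x + 5]))
        model = pca_fit(Z, alpha=0.5)
        assert model.k == 1
        assert model.contribution[0] == pytest.approx(1.0, abs=1e-9)

    def test_alpha_one_keeps_full_rank(self, rng):
        Z, _ = standardize(rng.normal(size=(30, 5)))
        model = pca_fit(Z, alpha=1.0)
        assert model.k == 5

    def test_shares_match_independent_eigensolver(self, rng):
        Z, _ = standardize(rng.normal(size=(30, 10)) @ rng.normal(size=(10, 10)))
        model = pca_fit(Z, alpha=0.98)
        # sklearn PCA as the independent oracle (covariance of z-scores
        # with ddof rescaling only affects absolute eigenvalues, not shares)
        ref = SkPCA().fit(Z)
        np.testing.assert_allclose(
            model.contribution, ref.explained_variance_ratio_, atol=1e-9
        )
        shares = np.cumsum(model.contribution)
        assert shares[model.k - 1] >= 0.98
        assert model.k == 1 or shares[model.k - 2] < 0.98

    def test_transform_consistency_and_ordering(self, rng):
        Z, _ = standardize(rng.normal(size=(40, 6)) @ rng.normal(size=(6, 6)))
        model = pca_fit(Z, alpha=0.9)
        scores = pca_transform(model, Z)
        variances = scores.var(axis=0)
        assert np.all(np.diff(variances) <= 1e-9)

    def test_full_rank_reconstruction(self, rng):
        Z, _ = standardize(rng.normal(size=(25, 6)))
        model = pca_fit(Z, alpha=1.0)
        scores = pca_transform(model, Z)
        back = scores @ model.loadings[:, : model.k].T
        np.testing.assert_allclose(back, Z, atol=1e-9)

    def test_unstandardized_input_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_fit(rng.uniform(10, 20, size=(20, 3)))


class TestSVM:
    def test_separable_clouds_perfect_training_fit(self, rng):
        X = np.vstack([rng.normal(0, 1, (50, 2)), rng.normal(6, 1, (50, 2))])
        y = np.repeat([0, 1], 50)
        clf = svm_train(X, y)
        assert np.mean(svm_predict(clf, X) == y) == 1.0

    def test_duplicating_training_samples_leaves_predictions_unchanged(self, rng):
        # in the hard-margin regime (separable data, large C) the decision
        # surface depends only on the support set, so duplicates are inert
        X = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(6, 1, (30, 3))])
        y = np.repeat([0, 1], 30)
        grid = rng.normal(3, 3, size=(40, 3))
        p1 = svm_predict(svm_train(X, y, C=1e6, gamma=0.5), grid)
        p2 = svm_predict(
            svm_train(np.vstack([X, X]), np.hstack([y, y]), C=1e6, gamma=0.5), grid
        )
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            svm_train(np.zeros((5, 2)), np.zeros(5))


class TestConfusionMetrics:
    @pytest.mark.parametrize(
        "tns,fps,fns,tps,accuracy",
        [(91, 6, 3, 25, 92.8), (92, 5, 6, 22, 91.2)],
    )
    def test_accuracy_from_counts(self, tns, fps, fns, tps, accuracy):
        m = confusion_metrics(ConfusionCounts(tns, fps, fns, tps))
        assert m["accuracy"] == pytest.approx(accuracy, abs=1e-9)

    def test_sensitivity_specificity(self):
        m = confusion_metrics(ConfusionCounts(tns=91, fps=6, fns=3, tps=25))
        assert m["sensitivity"] == pytest.approx(100 * 25 / 28)
        assert m["specificity"] == pytest.approx(100 * 91 / 97)
        assert m["undefined"] == []

    def test_zero_denominator_flagged(self):
        m = confusion_metrics(ConfusionCounts(tns=10, fps=2, fns=0, tps=0))
        assert np.isnan(m["sensitivity"])
        assert m["undefined"] == ["sensitivity"]

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionCounts(0, 0, 0, 0))


class TestRepeatedKFoldCV:
    def test_fold_protocol_125_samples(self):
        X, y = generate_feature_dataset(28, 97, n_features=20, separation=4.0, seed=3)
        runs = repeated_kfold_cv(X, y, k=5, repeats=3, seed=3)
        assert len(runs) == 3
        for run in runs:
            sizes = np.bincount(run.fold_assignments, minlength=5)
            assert list(sizes) == [25] * 5  # five folds of 25, n=125
            assert run.counts.n == 125  # every sample tested exactly once

    def test_folds_partition_and_results_consistent(self):
        X, y = generate_feature_dataset(20, 40, n_features=10, separation=3.0, seed=8)
        runs = repeated_kfold_cv(X, y, k=4, repeats=2, seed=8)
        for run in runs:
            assert run.fold_assignments.shape == (60,)
            assert set(run.fold_assignments) == {0, 1, 2, 3}
            c = run.counts
            assert run.test_accuracy == pytest.approx(100 * (c.tns + c.tps) / c.n)
            assert run.sensitivity == pytest.approx(100 * c.tps / (c.tps + c.fns))
            assert run.specificity == pytest.approx(100 * c.tns / (c.tns + c.fps))

    def test_repeats_differ_but_seed_reproduces(self):
        X, y = generate_feature_dataset(15, 30, n_features=8, separation=3.0, seed=4)
        a = repeated_kfold_cv(X, y, k=5, repeats=2, seed=4)
        b = repeated_kfold_cv(X, y, k=5, repeats=2, seed=4)
        assert [r.test_accuracy for r in a] == [r.test_accuracy for r in b]
        assert not np.array_equal(a[0].fold_assignments, a[1].fold_assignments)

    def test_separable_data_classified_accurately(self):
        X, y = generate_feature_dataset(28, 97, n_features=70, separation=6.0, seed=1)
        runs = repeated_kfold_cv(X, y, k=5, repeats=5, seed=1)
        assert summarize_runs(runs)["mean_test_accuracy"] >= 95.0

    def test_accuracy_increases_with_separation(self):
        accs = []
        for sep in (0.0, 2.0, 6.0):
            X, y = generate_feature_dataset(40, 60, n_features=15, separation=sep, seed=6)
            runs = repeated_kfold_cv(X, y, k=5, repeats=3, seed=6)
            accs.append(summarize_runs(runs)["mean_test_accuracy"])
        assert accs[0] < accs[2]
        assert accs[1] <= accs[2] + 2.0  # monotone within simulation error

    def test_combined_mode_runs_and_matches_protocol(self):
        X, y = generate_feature_dataset(28, 97, n_features=20, separation=4.0, seed=9)
        runs = repeated_kfold_cv(X, y, k=5, repeats=2, pca_mode="combined", seed=9)
        assert all(r.counts.n == 125 for r in runs)

    def test_single_class_training_fold_raises_with_diagnostics(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        y = np.array([1, 0, 0, 0, 0, 0])  # lone positive must land in some test fold
        with pytest.raises(ValueError, match="single"):
            repeated_kfold_cv(X, y, k=2, repeats=1, seed=0)

    def test_invalid_arguments(self):
        X, y = generate_feature_dataset(5, 5, n_features=4, seed=0)
        with pytest.raises(ValueError):
            repeated_kfold_cv(X, y, k=1)
        with pytest.raises(ValueError):
            repeated_kfold_cv(X, y, k=5, repeats=0)
        with pytest.raises(ValueError):
            repeated_kfold_cv(X, y, k=5, pca_mode="bogus")
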