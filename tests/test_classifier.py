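"""LDA fitting/prediction, stratified folds, and cross-validation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from optibiopsy.classifier import (
    ClassifierError,
    ConfusionMatrix,
    confusion_metrics,
    cross_validate,
    fit_lda,
    predict,
    stratified_kfold,
)

H, T = "healthy", "tumor"


def _labels(n_h, n_t):
    return np.array([H] * n_h + [T] * n_t)


def density_oracle(X_train, y_train, X_test, lam):
    """Reference LDA via explicit Gaussian density x prior comparison.

    Recomputes class means, the pooled (n-2 denominator) covariance and
    frequency priors from scratch and classifies by the larger
    log N(x; mu_k, S) + log pi_k, using scipy density evaluation.  Returns
    (labels, margin) where margin is the tumor-minus-healthy log score.
    """
    X_train = np.asarray(X_train, float)
    mus, ns = [], []
    scatter = np.zeros((X_train.shape[1],) * 2)
    for cls in (H, T):
        Xk = X_train[y_train == cls]
        mus.append(Xk.mean(axis=0))
        ns.append(len(Xk))
        scatter += (Xk - mus[-1]).T @ (Xk - mus[-1])
    cov = scatter / (len(X_train) - 2) + lam * np.eye(X_train.shape[1])
    logp = np.column_stack(
        [
            multivariate_normal.logpdf(X_test, mu, cov) + np.log(n / len(X_train))
            for mu, n in zip(mus, ns)
        ]
    )
    margin = logp[:, 1] - logp[:, 0]
    return np.where(margin > 0, T, H), margin


def _random_dataset(rng, d, n_h, n_t):
    A = rng.normal(size=(d, d))
    cov = A @ A.T + 0.5 * np.eye(d)
    mu_h = rng.normal(0.0, 1.0, size=d)
    mu_t = mu_h + rng.normal(0.0, 1.5, size=d)
    X = np.vstack(
        [
            rng.multivariate_normal(mu_h, cov, size=n_h),
            rng.multivariate_normal(mu_t, cov, size=n_t),
        ]
    )
    return X, _labels(n_h, n_t)


class TestFitPredict:
    def test_separated_clusters_recover_training_labels(self):
        rng = np.random.default_rng(0)
        X = np.vstack(
            [rng.normal(0.0, 0.1, (10, 2)), rng.normal(10.0, 0.1, (12, 2))]
        )
        y = _labels(10, 12)
        model = fit_lda(X, y)
        pred, _ = predict(model, X)
        assert (pred == y).all()

    def test_one_dimensional_threshold_matches_gaussian_oracle(self):
        """Training on N(0,1) vs N(2,1) puts the boundary near 1."""
        rng = np.random.default_rng(3)
        X = np.concatenate(
            [rng.normal(0.0, 1.0, 60), rng.normal(2.0, 1.0, 60)]
        ).reshape(-1, 1)
        y = _labels(60, 60)
        model = fit_lda(X, y, regularization_lambda=0.0)
        # with equal priors and a shared variance the threshold is the
        # midpoint of the class means
        threshold = model.class_means.mean()
        assert threshold == pytest.approx(1.0, abs=0.4)
        grid = np.linspace(-2.0, 4.0, 121).reshape(-1, 1)
        pred, _ = predict(model, grid)
        oracle, _ = density_oracle(X, y, grid, 0.0)
        assert (pred == oracle).all()

    def test_tie_at_midpoint_resolves_to_healthy(self):
        # symmetric clusters, equal counts: the midpoint scores tie exactly
        X = np.array([[-2.0, 0.0], [-2.5, 1.0], [2.0, 0.0], [2.5, 1.0]])
        y = _labels(2, 2)
        model = fit_lda(X, y, regularization_lambda=0.0)
        pred, scores = predict(model, np.array([[0.0, 0.5]]))
        assert scores[0, 0] == pytest.approx(scores[0, 1], abs=1e-12)
        assert pred[0] == H

    def test_singular_covariance_without_ridge_is_error(self):
        # a duplicated point in each class: zero within-class scatter
        X = np.array([[1.0, 2.0]] * 2 + [[3.0, 4.0]] * 2)
        y = _labels(2, 2)
        with pytest.raises(ClassifierError, match="lambda"):
            fit_lda(X, y, regularization_lambda=0.0)
        fit_lda(X, y, regularization_lambda=1e-6)  # ridge rescues it

    def test_small_class_rejected(self):
        X = np.zeros((3, 2))
        with pytest.raises(ClassifierError, match="at least 2"):
            fit_lda(X, np.array([H, T, T]))

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(1)
        X, y = _random_dataset(rng, 2, 5, 5)
        model = fit_lda(X, y)
        with pytest.raises(ClassifierError, match="dimension"):
            predict(model, np.zeros((3, 4)))

    def test_matches_density_oracle_on_random_datasets(self):
        """Predictions equal the density-comparison reference at non-ties."""
        rng = np.random.default_rng(2024)
        for _ in range(50):
            d = int(rng.choice([2, 4]))
            n_h = int(rng.integers(5, 21))
            n_t = int(rng.integers(5, 21))
            X, y = _random_dataset(rng, d, n_h, n_t)
            X_test = rng.normal(0.0, 2.0, size=(15, d))
            model = fit_lda(X, y, regularization_lambda=1e-8)
            pred, _ = predict(model, X_test)
            oracle, margin = density_oracle(X, y, X_test, 1e-8)
            decided = np.abs(margin) > 1e-9
            assert (pred[decided] == oracle[decided]).all()

    def test_matches_sklearn_on_balanced_datasets(self):
        """Cross-check against sklearn LDA where conventions coincide.

        sklearn pools the covariance with denominator n rather than n-2;
        with balanced classes the prior term vanishes and the covariance
        scale cancels in the argmax, so labels must agree exactly away
        from the boundary.
        """
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(77)
        for _ in range(20):
            d = int(rng.choice([2, 4]))
            n = int(rng.integers(6, 20))
            X, y = _random_dataset(rng, d, n, n)
            X_test = rng.normal(0.0, 2.0, size=(20, d))
            model = fit_lda(X, y, regularization_lambda=0.0)
            pred, _ = predict(model, X_test)
            sk = LinearDiscriminantAnalysis().fit(X, y)
            margin = sk.decision_function(X_test)
            decided = np.abs(margin) > 1e-9
            assert (pred[decided] == sk.predict(X_test)[decided]).all()

    def test_prediction_invariant_under_column_rescaling(self):
        """LDA is invariant to invertible affine feature maps."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            d = int(rng.choice([2, 4]))
            X, y = _random_dataset(rng, d, 12, 14)
            X_test = rng.normal(0.0, 2.0, size=(20, d))
            base, _ = predict(fit_lda(X, y, 0.0), X_test)
            c = float(rng.uniform(0.1, 10.0))
            col = int(rng.integers(d))
            Xs, Xts = X.copy(), X_test.copy()
            Xs[:, col] *= c
            Xts[:, col] *= c
            scaled, _ = predict(fit_lda(Xs, y, 0.0), Xts)
            assert (base == scaled).all()


class TestStratifiedKFold:
    def test_balanced_divisible_case(self):
        folds = stratified_kfold(_labels(10, 10), k=5, seed=0)
        for f in range(5):
            held = folds == f
            assert held.sum() == 4
            assert (_labels(10, 10)[held] == H).sum() == 2

    def test_study_sized_class_counts(self):
        # 24 healthy + 28 tumor over 5 folds
        y = _labels(24, 28)
        folds = stratified_kfold(y, k=5, seed=1)
        h_counts = [((folds == f) & (y == H)).sum() for f in range(5)]
        t_counts = [((folds == f) & (y == T)).sum() for f in range(5)]
        assert sorted(h_counts) == [4, 5, 5, 5, 5]
        assert sorted(t_counts) == [5, 5, 6, 6, 6]

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ClassifierError, match="stratify"):
            stratified_kfold(_labels(4, 10), k=5, seed=0)

    def test_pure_function_of_labels_k_seed(self):
        y = _labels(13, 17)
        a = stratified_kfold(y, 5, seed=9)
        b = stratified_kfold(y, 5, seed=9)
        c = stratified_kfold(y, 5, seed=10)
        assert (a == b).all()
        assert not (a == c).all()


class TestConfusionMetrics:
    def test_perfect_and_forced_arithmetic(self):
        assert confusion_metrics(ConfusionMatrix(tp=28, fp=0, tn=24, fn=0)) == (1.0, 1.0)
        sens, spec = confusion_metrics(ConfusionMatrix(tp=19, fp=2, tn=22, fn=1))
        assert sens == pytest.approx(0.95)
        assert spec == pytest.approx(22 / 24)

    def test_empty_classes_rejected(self):
        with pytest.raises(ClassifierError, match="sensitivity"):
            confusion_metrics(ConfusionMatrix(tp=0, fp=1, tn=1, fn=0))
        with pytest.raises(ClassifierError, match="specificity"):
            confusion_metrics(ConfusionMatrix(tp=1, fp=0, tn=0, fn=1))


def _feature_table(X, y, cols=("ratio1", "ratio2")):
    table = pd.DataFrame(X, columns=list(cols))
    table.insert(0, "tissue_label", y)
    for c in ("ratio1", "ratio2", "ratio3", "ratio4"):
        if c not in table.columns:
            table[c] = np.nan
    return table


class TestCrossValidate:
    def test_separable_clusters_score_perfectly(self):
        rng = np.random.default_rng(4)
        X = np.vstack(
            [rng.normal(0.0, 0.1, (20, 2)), rng.normal(5.0, 0.1, (20, 2))]
        )
        report = cross_validate(_feature_table(X, _labels(20, 20)), "drs", seed=0)
        assert report.sensitivity == 1.0
        assert report.specificity == 1.0
        assert report.pooled.total == 40

    def test_identical_seed_gives_identical_report(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 2))
        table = _feature_table(X, _labels(15, 15))
        a = cross_validate(table, "drs", seed=5)
        b = cross_validate(table, "drs", seed=5)
        assert a.to_json() == b.to_json()

    def test_rows_missing_selected_columns_are_dropped(self):
        rng = np.random.default_rng(8)
        X = np.vstack(
            [rng.normal(0.0, 0.1, (12, 2)), rng.normal(5.0, 0.1, (12, 2))]
        )
        table = _feature_table(X, _labels(12, 12))
        table.loc[3, "ratio1"] = np.nan
        report = cross_validate(table, "drs", seed=0)
        assert report.dropped_rows == 1
        assert report.pooled.total == 23
        # AF model uses different columns: nothing to drop, but all-NaN
        with pytest.raises(ClassifierError):
            cross_validate(table, "af", seed=0)

    def test_combined_model_tracks_drs_when_af_is_noise(self):
        """Pure-noise AF columns must not corrupt the combined model."""
        rng = np.random.default_rng(12)
        n = 200
        X_drs = np.vstack(
            [rng.normal(0.0, 1.0, (n, 2)), rng.normal(2.5, 1.0, (n, 2))]
        )
        table = _feature_table(X_drs, _labels(n, n))
        table["ratio3"] = rng.normal(size=2 * n)
        table["ratio4"] = rng.normal(size=2 * n)
        drs = cross_validate(table, "drs", seed=3)
        combined = cross_validate(table, "combined", seed=3)
        assert abs(combined.pooled.accuracy - drs.pooled.accuracy) <= 0.1

    def test_unknown_config_rejected(self):
        with pytest.raises(ClassifierError, match="model_config"):
            cross_validate(_feature_table(np.zeros((4, 2)), _labels(2, 2)), "pca")
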