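import json

import numpy as np
import pytest

from subshape.classifier import (
    NotFittedError,
    PCALDAClassifier,
    fit_lda,
    fit_pca,
    predict_subject,
    train_batch,
    update_incremental,
)


def two_gaussians(n_pos=30, n_neg=50, dim=10, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_pos + n_neg, dim))
    y = np.r_[np.ones(n_pos, int), np.zeros(n_neg, int)]
    X[y == 1, 0] += sep
    return X, y


class TestPCA:
    def test_equal_variance_ten_directions(self):
        # 10 orthogonal directions each explaining exactly 10% of the
        # variance: the 70% rule keeps exactly 7
        X = np.vstack([np.eye(10), -np.eye(10)])
        pca = fit_pca(X, 0.70)
        assert pca.d == 7

    def test_single_direction(self):
        t = np.linspace(-1, 1, 20)[:, None]
        X = t @ np.array([[1.0, 2.0, -1.0]])
        pca = fit_pca(X, 0.70)
        assert pca.d == 1

    def test_full_fraction_keeps_rank(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 5)) @ rng.normal(size=(5, 12))  # rank 5
        pca = fit_pca(X, 1.0)
        assert pca.d == 5

    def test_components_orthonormal_variances_sorted(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 8)) * np.arange(1, 9)
        pca = fit_pca(X, 0.95)
        G = pca.components.T @ pca.components
        assert np.abs(G - np.eye(pca.d)).max() < 1e-8
        assert (np.diff(pca.variances) <= 1e-10).all()

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_pca(np.ones((5, 3)), 0.7)

    def test_matches_sklearn_oracle(self):
        from sklearn.decomposition import PCA as SkPCA

        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 12)) * np.linspace(3, 0.2, 12)
        pca = fit_pca(X, 0.9)
        sk = SkPCA().fit(X)
        assert np.allclose(pca.variances, sk.explained_variance_[: pca.d], rtol=1e-8)
        # same subspace up to sign
        dots = np.abs(np.einsum("ij,ij->j", pca.components,
                                sk.components_[: pca.d].T))
        assert np.allclose(dots, 1.0, atol=1e-6)


class TestLDA:
    def test_closed_form_direction(self):
        rng = np.random.default_rng(0)
        for seed in range(10):
            X, y = two_gaussians(dim=2, sep=3.0, seed=seed)
            lda = fit_lda(X, y)
            Sw = sum(
                (X[y == k] - X[y == k].mean(0)).T @ (X[y == k] - X[y == k].mean(0))
                for k in (0, 1)
            )
            w_ref = np.linalg.solve(Sw, X[y == 1].mean(0) - X[y == 0].mean(0))
            w_ref /= np.linalg.norm(w_ref)
            assert abs(lda.w @ w_ref) >= 0.9999

    def test_separated_1d_perfect_training_accuracy(self):
        X = np.r_[np.full((10, 1), -3.0), np.full((10, 1), 3.0)]
        X += np.random.default_rng(0).normal(scale=0.1, size=X.shape)
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        clf = train_batch(X, y, variance_fraction=1.0)
        assert (clf.predict(X) == y).all()

    def test_label_swap_negates_scores(self):
        X, y = two_gaussians(seed=4)
        s1 = train_batch(X, y).decision_function(X)
        s2 = train_batch(X, 1 - y).decision_function(X)
        assert np.allclose(s1, -s2, atol=1e-10)

    def test_class_means_straddle_threshold(self):
        X, y = two_gaussians(seed=5)
        clf = train_batch(X, y)
        lda = clf.lda_
        assert (lda.w @ lda.mean_pos - lda.threshold) > 0
        assert (lda.w @ lda.mean_neg - lda.threshold) < 0


class TestBatchTraining:
    def test_planted_effect_training_accuracy(self):
        # effect 2x the noise SD in each of four independent blocks
        # (mimicking a bilateral multi-structure pattern)
        rng = np.random.default_rng(6)
        X = rng.normal(size=(68, 40))
        y = np.r_[np.ones(23, int), np.zeros(45, int)]
        X[y == 1, 0:4] += 2.0
        clf = train_batch(X, y)
        assert np.mean(clf.predict(X) == y) >= 0.95

    def test_n_much_less_than_p(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 280))
        y = (rng.random(60) < 0.4).astype(int)
        clf = train_batch(X, y)  # PCA prevents the singularity
        assert clf.pca_.d < 60

    def test_permuted_labels_no_spurious_perfection(self):
        # with 70% variance PCA, permuted labels do not yield perfect
        # training separation at n=68
        accs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(68, 100)) * np.r_[np.linspace(3, 0.5, 20),
                                                   np.full(80, 0.2)]
            y = np.r_[np.ones(23, int), np.zeros(45, int)]
            y = rng.permutation(y)
            clf = train_batch(X, y)
            accs.append(np.mean(clf.predict(X) == y))
        assert 0.5 <= np.mean(accs) <= 0.85

    def test_mean_shift_invariance(self):
        X, y = two_gaussians(seed=8)
        s1 = train_batch(X, y).decision_function(X)
        shift = np.full(X.shape[1], 13.7)
        s2 = train_batch(X + shift, y).decision_function(X + shift)
        assert np.allclose(s1, s2, atol=1e-8)


class TestIncremental:
    def test_single_batch_equals_fit(self):
        X, y = two_gaussians(seed=9)
        Xt, _ = two_gaussians(n_pos=25, n_neg=25, seed=10)
        a = train_batch(X, y)
        b = PCALDAClassifier().partial_fit(X, y)
        assert np.array_equal(a.predict(Xt), b.predict(Xt))

    @pytest.mark.parametrize("batch_size", [5, 10, 17])
    def test_batched_equals_batch(self, batch_size):
        X, y = two_gaussians(n_pos=23, n_neg=45, dim=30, sep=1.0, seed=11)
        Xt, _ = two_gaussians(n_pos=25, n_neg=25, dim=30, seed=12)
        batch = train_batch(X, y)
        inc = PCALDAClassifier()
        rng = np.random.default_rng(13)
        order = rng.permutation(len(y))
        for start in range(0, len(y), batch_size):
            idx = order[start : start + batch_size]
            inc = update_incremental(inc, X[idx], y[idx])
        assert np.array_equal(batch.predict(Xt), inc.predict(Xt))

    def test_sufficient_statistics_match_batch_moments(self):
        X, y = two_gaussians(seed=14)
        inc = PCALDAClassifier()
        for start in range(0, len(y), 20):
            inc.partial_fit(X[start : start + 20], y[start : start + 20])
        for cls in (0, 1):
            Xc = X[y == cls]
            assert np.allclose(inc._sums[cls], Xc.sum(0), atol=1e-9)
            assert np.allclose(inc._sqsums[cls], Xc.T @ Xc, atol=1e-8)

    def test_feature_length_mismatch(self):
        X, y = two_gaussians(seed=15)
        inc = PCALDAClassifier().fit(X, y)
        with pytest.raises(ValueError, match="feature length"):
            inc.partial_fit(X[:, :5], y)


class TestPrediction:
    def test_positive_mean_predicted_positive(self):
        X, y = two_gaussians(seed=16)
        clf = train_batch(X, y)
        label, score = predict_subject(clf, X[y == 1].mean(0))
        assert label == 1 and score > 0

    def test_tie_goes_positive(self):
        X, y = two_gaussians(seed=17)
        clf = train_batch(X, y)
        # construct a feature scoring exactly zero: midpoint of the
        # projected class means along w, at the PCA mean elsewhere
        mid = 0.5 * (clf.lda_.mean_pos + clf.lda_.mean_neg)
        x0 = clf.pca_.mean + clf.pca_.components @ mid
        label, score = predict_subject(clf, x0)
        assert abs(score) < 1e-10
        assert label == 1

    def test_untrained_errors(self):
        with pytest.raises(NotFittedError):
            PCALDAClassifier().predict(np.zeros((1, 3)))

    def test_oracle_agreement_sklearn_lda(self):
        # PCA at full variance + our LDA vs sklearn LDA on the same
        # reduced data: identical labels on 100 random test subjects
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(18)
        X, y = two_gaussians(n_pos=40, n_neg=60, dim=6, sep=1.5, seed=19)
        Xt = rng.normal(size=(100, 6)) + 0.75
        ours = train_batch(X, y, variance_fraction=1.0)
        sk = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, y)
        assert np.array_equal(ours.predict(Xt), sk.predict(Xt))

    def test_get_params_round_trip(self):
        clf = PCALDAClassifier(variance_fraction=0.8, priors_weighted=True)
        params = clf.get_params()
        clone = PCALDAClassifier(**params)
        assert clone.variance_fraction == 0.8 and clone.priors_weighted


class TestSerialization:
    def test_json_round_trip_predictions(self):
        X, y = two_gaussians(seed=20)
        Xt, _ = two_gaussians(seed=21)
        clf = train_batch(X, y)
        restored = PCALDAClassifier.from_dict(
            json.loads(json.dumps(clf.to_dict()))
        )
        assert np.array_equal(clf.predict(Xt), restored.predict(Xt))
        assert np.allclose(
            clf.decision_function(Xt), restored.decision_function(Xt), atol=1e-10
        )

    def test_version_check(self):
        with pytest.raises(ValueError, match="version"):
            PCALDAClassifier.from_dict({"format_version": 99})
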