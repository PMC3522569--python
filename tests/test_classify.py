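"""The five classifiers: OVO voting, class weighting, kNN, Naive Bayes and
MAPLSC, against constructed geometries and closed-form baselines."""

import warnings

import numpy as np
import pytest
from scipy.stats import norm

from lipdx.classify import (
    MAPLSC,
    SVMConfig,
    class_weights,
    knn_predict,
    maplsc_fit_predict,
    nb_fit_predict,
    predict_vote,
    train_ovo_svm,
    train_wsvm,
)
from lipdx.errors import ParameterError


def _blobs(seed, centers, n=40, sd=0.3, p=2):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for label, c in centers.items():
        X.append(rng.normal(0, sd, (n, p)) + np.asarray(c))
        y.extend([label] * n)
    return np.vstack(X), np.array(y, dtype=object)


class TestOvoSVM:
    def test_four_classes_give_six_machines(self):
        X, y = _blobs(0, {"a": (0, 0), "b": (3, 0), "c": (0, 3), "d": (3, 3)})
        ens = train_ovo_svm(X, y)
        assert len(ens.machines) == 6

    def test_separable_data_training_accuracy_one(self):
        X, y = _blobs(1, {"a": (0, 0), "b": (6, 0), "c": (0, 6)}, sd=0.2)
        ens = train_ovo_svm(X, y, SVMConfig(kernel="linear"))
        assert np.mean(ens.predict(X) == y) == 1.0

    def test_prediction_only_returns_training_labels(self):
        X, y = _blobs(2, {"a": (0, 0), "b": (4, 0), "c": (0, 4), "d": (4, 4)})
        ens = train_ovo_svm(X, y)
        rng = np.random.default_rng(3)
        preds = ens.predict(rng.normal(0, 5, (50, 2)))
        assert set(preds) <= set(y)

    def test_majority_of_own_machines_wins(self):
        # a point deep inside class "a": all three machines involving "a"
        # vote "a", a strict majority over four classes
        X, y = _blobs(4, {"a": (0, 0), "b": (8, 0), "c": (0, 8), "d": (8, 8)}, sd=0.2)
        ens = train_ovo_svm(X, y)
        assert predict_vote(ens, np.array([0.0, 0.0])) == "a"

    def test_deterministic(self):
        X, y = _blobs(5, {"a": (0, 0), "b": (2, 0)})
        q = np.array([[1.0, 0.3]])
        a = train_ovo_svm(X, y).predict(q)
        b = train_ovo_svm(X, y).predict(q)
        assert a[0] == b[0]

    def test_affine_feature_rescaling_then_standardization_is_invariant(self):
        from lipdx.evaluate import standardize

        X, y = _blobs(6, {"a": (0, 0), "b": (3, 1)})
        q = np.array([[1.5, 0.5], [0.1, 0.2]])
        Xs, qs, _ = standardize(X, q)
        X2 = X.copy()
        X2[:, 0] = X2[:, 0] * 7.0 - 3.0
        q2 = q.copy()
        q2[:, 0] = q2[:, 0] * 7.0 - 3.0
        X2s, q2s, _ = standardize(X2, q2)
        a = train_ovo_svm(Xs, y).predict(qs)
        b = train_ovo_svm(X2s, y).predict(q2s)
        assert np.array_equal(a, b)


class TestClassWeights:
    def test_inverse_ratio_on_clinical_sizes(self):
        w = class_weights({"Deep-red": 90, "Pale": 12})
        assert w["Deep-red"] == 1.0
        assert w["Pale"] == pytest.approx(90 / 12)  # 7.5

    def test_equal_sizes_all_one(self):
        assert set(class_weights({"a": 5, "b": 5, "c": 5}).values()) == {1.0}

    def test_invariant_to_rescaling_sizes(self):
        a = class_weights({"x": 10, "y": 40})
        b = class_weights({"x": 30, "y": 120})
        assert a == b

    def test_zero_size_rejected(self):
        with pytest.raises(ParameterError):
            class_weights({"a": 0, "b": 5})

    def test_wsvm_equals_svm_on_balanced_classes(self):
        X, y = _blobs(7, {"a": (0, 0), "b": (2, 1), "c": (1, 3)}, n=30)
        q = np.random.default_rng(8).normal(1, 1.5, (40, 2))
        assert np.array_equal(train_wsvm(X, y).predict(q), train_ovo_svm(X, y).predict(q))


class TestKnn:
    def test_k1_returns_own_label_on_training_point(self):
        X, y = _blobs(9, {"a": (0, 0), "b": (3, 3)})
        assert knn_predict(X, y, X[5], k=1)[0] == y[5]

    def test_two_distant_clusters_recovered(self):
        X, y = _blobs(10, {"a": (0, 0), "b": (50, 50)}, sd=1.0)
        rng = np.random.default_rng(11)
        queries = np.vstack([rng.normal(0, 1, (20, 2)), rng.normal(50, 1, (20, 2))])
        expect = np.array(["a"] * 20 + ["b"] * 20, dtype=object)
        assert np.mean(knn_predict(X, y, queries, k=5) == expect) == 1.0

    def test_matches_allpairs_bruteforce(self):
        rng = np.random.default_rng(12)
        X = rng.normal(0, 1, (30, 3))
        y = np.array(list("abc") * 10, dtype=object)
        queries = rng.normal(0, 1, (10, 3))
        for k in (1, 3, 7):
            got = knn_predict(X, y, queries, k=k)
            for qi, q in enumerate(queries):
                d = np.sqrt(((X - q) ** 2).sum(1))
                nearest = sorted(range(30), key=lambda i: (d[i], i))[:k]
                votes = {}
                for i in nearest:
                    votes[y[i]] = votes.get(y[i], 0) + 1
                best = sorted(votes, key=lambda c: (-votes[c], c))[0]
                assert got[qi] == best

    def test_parameter_errors(self):
        X, y = _blobs(13, {"a": (0, 0), "b": (1, 1)}, n=5)
        with pytest.raises(ParameterError):
            knn_predict(X, y, X[0], k=0)
        with pytest.raises(ParameterError):
            knn_predict(X, y, X[0], k=11)


class TestNaiveBayes:
    def test_midpoint_of_symmetric_classes_is_fifty_fifty(self):
        rng = np.random.default_rng(14)
        X = np.concatenate([rng.normal(-2, 1, 200), rng.normal(2, 1, 200)])
        # symmetrize the samples exactly so the fitted Gaussians mirror
        X = np.concatenate([X[:200], -X[:200]]).reshape(-1, 1)
        y = np.array(["lo"] * 200 + ["hi"] * 200, dtype=object)
        _, post, classes = nb_fit_predict(X, y, np.array([[0.0]]))
        np.testing.assert_allclose(post[0], [0.5, 0.5], atol=1e-9)

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(15)
        X = rng.normal(0, 1, (60, 4))
        y = np.array(list("abc") * 20, dtype=object)
        _, post, _ = nb_fit_predict(X, y, rng.normal(0, 1, (10, 4)))
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_error_near_analytic_bayes_rate(self):
        # two univariate unit-variance Gaussians at +/- delta: the Bayes
        # error is Phi(-delta)
        delta = 1.0
        rng = np.random.default_rng(16)
        n = 5000
        Xtr = np.concatenate([rng.normal(-delta, 1, n), rng.normal(delta, 1, n)]).reshape(-1, 1)
        ytr = np.array(["a"] * n + ["b"] * n, dtype=object)
        Xte = np.concatenate([rng.normal(-delta, 1, n), rng.normal(delta, 1, n)]).reshape(-1, 1)
        yte = np.array(["a"] * n + ["b"] * n, dtype=object)
        pred, _, _ = nb_fit_predict(Xtr, ytr, Xte)
        err = np.mean(pred != yte)
        assert abs(err - norm.cdf(-delta)) < 0.02


class TestMaplsc:
    def test_coupled_posteriors_sum_to_one(self):
        X, y = _blobs(17, {"a": (0, 0), "b": (2, 0), "c": (0, 2), "d": (2, 2)}, sd=0.8)
        model = MAPLSC().fit(X, y)
        rng = np.random.default_rng(18)
        post = model.predict_proba(rng.normal(1, 2, (25, 2)))
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-6)

    def test_agrees_with_ovo_svm_on_balanced_separable_data(self):
        X, y = _blobs(19, {"a": (0, 0), "b": (6, 0)}, n=60, sd=0.5)
        Xte, yte = _blobs(20, {"a": (0, 0), "b": (6, 0)}, n=60, sd=0.5)
        svm_pred = train_ovo_svm(X, y).predict(Xte)
        mp_pred, _, _ = maplsc_fit_predict(X, y, Xte)
        assert np.mean(svm_pred == mp_pred) >= 0.95

    def test_minority_recall_beats_unweighted_threshold(self):
        """Under 90:12-style imbalance the equal-prior latent-score posterior
        recovers more minority samples than thresholding the raw PLS
        regression output at 0.5 (which is dragged toward the majority)."""
        from sklearn.cross_decomposition import PLSRegression

        gains = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            Xmaj = rng.normal(0.0, 1.0, (90, 5))
            Xmin = rng.normal(1.5, 1.0, (12, 5))
            X = np.vstack([Xmaj, Xmin])
            y = np.array(["maj"] * 90 + ["min"] * 12, dtype=object)
            Xte = rng.normal(1.5, 1.0, (50, 5))  # minority-class queries
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mp, _, _ = maplsc_fit_predict(X, y, Xte)
                pls = PLSRegression(n_components=2, scale=False).fit(X, (y == "min").astype(float))
            base = np.where(pls.predict(Xte).ravel() > 0.5, "min", "maj")
            gains.append(np.mean(mp == "min") - np.mean(base == "min"))
        assert np.mean(gains) > 0.0

    def test_fallback_on_degenerate_projection(self):
        X = np.zeros((20, 3))
        y = np.array(["a"] * 15 + ["b"] * 5, dtype=object)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MAPLSC().fit(X, y)
            post = model.predict_proba(np.zeros((1, 3)))
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-6)
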