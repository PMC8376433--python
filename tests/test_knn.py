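import numpy as np
import pytest

from doaeeg.knn import (DistanceSpec, distance, knn_fit, knn_predict,
                        pairwise_distance)


def formula_oracle(v, w, name, p=3.0, S=None, C=None):
    """Longhand implementations of the eight metric formulas."""
    v, w = np.asarray(v, float), np.asarray(w, float)
    d = v - w
    if name == "euclidean":
        return np.sqrt(np.sum(d ** 2))
    if name == "std_euclidean":
        return np.sqrt(np.sum(d ** 2 / S ** 2))
    if name == "minkowski":
        return np.sum(np.abs(d) ** p) ** (1 / p)
    if name == "chebyshev":
        return np.max(np.abs(d))
    if name == "cityblock":
        return np.sum(np.abs(d))
    if name == "cosine":
        return 1 - v @ w / np.sqrt((v @ v) * (w @ w))
    if name == "correlation":
        vc, wc = v - v.mean(), w - w.mean()
        return 1 - vc @ wc / np.sqrt((vc @ vc) * (wc @ wc))
    if name == "mahalanobis":
        return np.sqrt(d @ np.linalg.inv(C) @ d)
    raise ValueError(name)


def random_spd(rng, n):
    A = rng.normal(size=(n, n))
    return A @ A.T + n * np.eye(n)


class TestDistanceFormulas:
    def test_three_four_five_triangle(self):
        v, w = np.array([0.0, 0.0]), np.array([3.0, 4.0])
        assert distance(v, w, DistanceSpec("euclidean")) == pytest.approx(5.0)
        assert distance(v, w, DistanceSpec("cityblock")) == pytest.approx(7.0)
        assert distance(v, w, DistanceSpec("chebyshev")) == pytest.approx(4.0)

    def test_minkowski_special_cases(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            v, w = rng.normal(size=(2, 6))
            d1 = distance(v, w, DistanceSpec("minkowski", p=1))
            d2 = distance(v, w, DistanceSpec("minkowski", p=2))
            assert d1 == pytest.approx(
                distance(v, w, DistanceSpec("cityblock")), abs=1e-12)
            assert d2 == pytest.approx(
                distance(v, w, DistanceSpec("euclidean")), abs=1e-12)

    def test_mahalanobis_identity_covariance_is_euclidean(self):
        rng = np.random.default_rng(1)
        spec = DistanceSpec("mahalanobis", C=np.eye(5))
        for _ in range(20):
            v, w = rng.normal(size=(2, 5))
            assert distance(v, w, spec) == pytest.approx(
                distance(v, w, DistanceSpec("euclidean")), abs=1e-10)

    def test_parallel_and_anticorrelated_vectors(self):
        v = np.array([1.0, 2.0, 3.0])
        assert distance(v, 2 * v, DistanceSpec("cosine")) == pytest.approx(0.0, abs=1e-12)
        centered = v - v.mean()
        assert distance(centered, -centered + 5.0,
                        DistanceSpec("correlation")) == pytest.approx(2.0)

    def test_all_eight_match_formula_oracle(self):
        rng = np.random.default_rng(2)
        n = 7
        S = rng.uniform(0.5, 2.0, n)
        C = random_spd(rng, n)
        specs = {
            "euclidean": DistanceSpec("euclidean"),
            "std_euclidean": DistanceSpec("std_euclidean", S=S),
            "minkowski": DistanceSpec("minkowski", p=3.0),
            "chebyshev": DistanceSpec("chebyshev"),
            "cityblock": DistanceSpec("cityblock"),
            "cosine": DistanceSpec("cosine"),
            "correlation": DistanceSpec("correlation"),
            "mahalanobis": DistanceSpec("mahalanobis", C=C),
        }
        for _ in range(20):
            v, w = rng.normal(size=(2, n))
            for name, spec in specs.items():
                assert distance(v, w, spec) == pytest.approx(
                    formula_oracle(v, w, name, S=S, C=C), abs=1e-10), name

    def test_metric_axioms_spot_check(self):
        rng = np.random.default_rng(3)
        for name in ("euclidean", "cityblock", "chebyshev", "minkowski"):
            spec = DistanceSpec(name, p=3.0)
            for _ in range(20):
                a, b, c = rng.normal(size=(3, 5))
                dab = distance(a, b, spec)
                assert dab >= 0
                assert dab == pytest.approx(distance(b, a, spec), abs=1e-12)
                assert dab <= distance(a, c, spec) + distance(c, b, spec) + 1e-12

    def test_zero_vector_rejected_for_angular_metrics(self):
        z = np.zeros(4)
        with pytest.raises(ValueError):
            distance(z, np.ones(4), DistanceSpec("cosine"))
        with pytest.raises(ValueError):
            distance(np.ones(4), np.ones(4) * 2, DistanceSpec("correlation"))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            DistanceSpec("hamming")
        with pytest.raises(ValueError):
            DistanceSpec("minkowski", p=0.5)
        with pytest.raises(ValueError):
            DistanceSpec("std_euclidean", S=np.array([1.0, 0.0]))


class TestFitting:
    def test_basic_fit_and_query(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 3))
        y = np.array(["D", "A"] * 5)
        model = knn_fit(X, y, K=3, metric="euclidean")
        assert len(knn_predict(model, X[:2])) == 2

    def test_k_larger_than_train_rejected(self):
        with pytest.raises(ValueError):
            knn_fit(np.zeros((3, 2)), np.array(["D"] * 3), K=4)

    def test_constant_feature_scale_floored_with_warning(self):
        X = np.column_stack([np.arange(6.0), np.full(6, 2.0)])
        y = np.array(["D", "A"] * 3)
        with pytest.warns(UserWarning):
            model = knn_fit(X, y, K=1, metric="std_euclidean")
        assert np.all(model.spec.S > 0)
        assert np.all(np.isfinite(knn_predict(model, X) != None))

    def test_singular_covariance_gets_ridge(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(2, 60))  # 2 samples in 60 dims: singular
        y = np.array(["D", "A"])
        model = knn_fit(X, y, K=1, metric="mahalanobis")
        assert model.ridge > 0
        d = pairwise_distance(X[:1], X[1:], model.spec)
        assert np.isfinite(d).all()


class TestPrediction:
    def test_query_on_training_point_returns_its_label(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 4))
        y = np.array(["D", "A", "S", "A"] * 5)
        model = knn_fit(X, y, K=1, metric="euclidean")
        assert np.array_equal(knn_predict(model, X), y)

    def test_separated_blobs_classified_perfectly(self):
        rng = np.random.default_rng(7)
        c1 = rng.normal(0, 1, size=(30, 5))
        c2 = rng.normal(0, 1, size=(30, 5)) + 20.0  # 20 sigma apart
        X = np.vstack([c1, c2])
        y = np.array(["D"] * 30 + ["S"] * 30)
        model = knn_fit(X, y, K=5, metric="euclidean")
        q = np.vstack([rng.normal(0, 1, size=(10, 5)),
                       rng.normal(0, 1, size=(10, 5)) + 20.0])
        expected = np.array(["D"] * 10 + ["S"] * 10)
        assert np.array_equal(knn_predict(model, q), expected)

    def test_matches_brute_force_vote_oracle(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 6))
        y = rng.choice(["D", "A", "S"], size=40)
        K = 5
        model = knn_fit(X, y, K=K, metric="cityblock")
        Q = rng.normal(size=(50, 6))
        pred = knn_predict(model, Q)
        for i in range(50):
            d = np.abs(X - Q[i]).sum(axis=1)
            idx = np.argsort(d)[:K]
            votes = {}
            for j in idx:
                votes.setdefault(y[j], []).append(d[j])
            rank = {"D": 0, "A": 1, "S": 2}
            best = min(votes.items(),
                       key=lambda kv: (-len(kv[1]), sum(kv[1]), rank[kv[0]]))
            assert pred[i] == best[0]

    def test_invariant_to_training_row_permutation(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 4))
        y = rng.choice(["D", "A", "S"], size=30)
        Q = rng.normal(size=(15, 4))
        perm = rng.permutation(30)
        p1 = knn_predict(knn_fit(X, y, K=3, metric="euclidean"), Q)
        p2 = knn_predict(knn_fit(X[perm], y[perm], K=3, metric="euclidean"), Q)
        assert np.array_equal(p1, p2)

    def test_std_euclidean_absorbs_feature_rescaling(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(30, 4))
        y = rng.choice(["D", "A"], size=30)
        Q = rng.normal(size=(10, 4))
        scale = np.array([1.0, 50.0, 0.02, 7.0])
        p1 = knn_predict(knn_fit(X, y, K=3, metric="std_euclidean"), Q)
        p2 = knn_predict(knn_fit(X * scale, y, K=3, metric="std_euclidean"),
                         Q * scale)
        assert np.array_equal(p1, p2)

    def test_dimension_mismatch_rejected(self):
        model = knn_fit(np.zeros((4, 3)), np.array(["D"] * 4), K=1,
                        metric="euclidean")
        with pytest.raises(ValueError):
            knn_predict(model, np.zeros((2, 5)))
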