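"""Risk network: prediction, gradients, training, LOOCV, ROC."""

import numpy as np
import pytest
import sklearn.metrics

from pjaplan import RiskModel, Standardizer, TrainConfig, accuracy, loocv, roc_auc, train


def _random_model(rng, n_features=6, hidden=4, with_std=False):
    model = RiskModel(
        W1=rng.normal(size=(hidden, n_features)),
        b1=rng.normal(size=hidden),
        w2=rng.normal(size=hidden),
        b2=float(rng.normal()),
    )
    if with_std:
        model.standardizer = Standardizer(
            mean=rng.normal(size=n_features), scale=rng.uniform(0.5, 2.0, n_features))
    return model


def test_zero_weights_predict_one_half():
    model = RiskModel(W1=np.zeros((4, 18)), b1=np.zeros(4), w2=np.zeros(4), b2=0.0)
    assert model.predict_one(np.random.default_rng(0).normal(size=18)) == 0.5


def test_predictions_stay_strictly_inside_unit_interval(rng):
    model = _random_model(rng)
    X = rng.normal(scale=50.0, size=(100, 6))
    y = model.predict(X)
    assert ((y > 0) & (y < 1)).all()


def test_input_gradient_matches_finite_differences(rng):
    for k in range(5):
        model = _random_model(rng, with_std=bool(k % 2))
        x = rng.normal(size=6)
        g = model.input_gradient(x)
        h = 1e-6
        for j in range(6):
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            fd = (model.predict_one(xp) - model.predict_one(xm)) / (2 * h)
            assert g[j] == pytest.approx(fd, rel=1e-5, abs=1e-10)


def test_weight_gradients_match_finite_differences(rng):
    model = _random_model(rng)
    Z = rng.normal(size=(7, 6))
    t = rng.integers(0, 2, size=7).astype(float)
    _, grads = model._loss_and_gradients(Z, t)
    h = 1e-6
    for name in ("W1", "b1", "w2"):
        arr = getattr(model, name)
        it = np.ndindex(arr.shape)
        for idx in it:
            orig = arr[idx]
            arr[idx] = orig + h
            lp, _ = model._loss_and_gradients(Z, t)
            arr[idx] = orig - h
            lm, _ = model._loss_and_gradients(Z, t)
            arr[idx] = orig
            fd = (lp - lm) / (2 * h)
            assert grads[name][idx] == pytest.approx(fd, rel=1e-5, abs=1e-9)
    model.b2 += h
    lp, _ = model._loss_and_gradients(Z, t)
    model.b2 -= 2 * h
    lm, _ = model._loss_and_gradients(Z, t)
    model.b2 += h
    assert grads["b2"][0] == pytest.approx((lp - lm) / (2 * h), rel=1e-5, abs=1e-9)


def test_training_is_bit_reproducible(rng):
    X = rng.normal(size=(20, 5))
    y = (X[:, 0] > 0).astype(float)
    cfg = TrainConfig(seed=7, epochs=200)
    m1, h1 = train(X, y, cfg)
    m2, h2 = train(X, y, cfg)
    assert (m1.W1 == m2.W1).all() and (m1.w2 == m2.w2).all()
    assert m1.b2 == m2.b2 and (h1 == h2).all()


def test_separable_toy_problem_reaches_low_mse(rng):
    X = np.column_stack([np.linspace(-2, 2, 20), rng.normal(size=20)])
    y = (X[:, 0] > 0).astype(float)
    _, history = train(X, y, TrainConfig(seed=0))
    assert history[-1] < 0.05
    assert history[-1] <= history[0]


def test_single_class_training_warns(rng):
    X = rng.normal(size=(6, 3))
    with pytest.warns(UserWarning, match="single class"):
        train(X, np.zeros(6), TrainConfig(seed=0, epochs=10))


def test_trained_risk_is_monotone_in_single_driving_feature(rng):
    X = np.linspace(-2.0, 2.0, 40).reshape(-1, 1)
    y = (X[:, 0] > 0).astype(float)
    model, _ = train(X, y, TrainConfig(seed=1))
    risks = model.predict(np.linspace(-2.0, 2.0, 200).reshape(-1, 1))
    assert (np.diff(risks) >= -1e-9).all()


def test_serialization_round_trip(tmp_path, rng):
    X = rng.normal(size=(15, 4))
    y = (X[:, 1] > 0).astype(float)
    model, _ = train(X, y, TrainConfig(seed=3, epochs=100))
    path = tmp_path / "model.json"
    model.to_json(path)
    clone = RiskModel.from_json(path)
    x = rng.normal(size=4)
    assert clone.predict_one(x) == pytest.approx(model.predict_one(x), rel=0, abs=0)
    assert clone.config == model.config


class TestLoocv:
    def test_fold_count_and_held_out_predictions(self, rng):
        X = rng.normal(size=(12, 3))
        y = np.array([0] * 9 + [1] * 3, dtype=float)
        res = loocv(X, y, TrainConfig(seed=0, epochs=50))
        assert res.risks.shape == (12,)
        assert res.labels.tolist() == y.tolist()

    def test_high_accuracy_on_separable_toy(self, rng):
        X = np.column_stack([np.r_[rng.normal(-2, 0.3, 10), rng.normal(2, 0.3, 10)],
                             rng.normal(size=20)])
        y = np.r_[np.zeros(10), np.ones(10)]
        res = loocv(X, y, TrainConfig(seed=0, epochs=500))
        assert res.accuracy >= 0.9
        assert res.auc >= 0.9

    def test_minimum_cohort_size(self, rng):
        with pytest.raises(ValueError):
            loocv(rng.normal(size=(2, 3)), np.array([0.0, 1.0]))

    def test_single_class_folds_are_recorded(self, rng):
        X = rng.normal(size=(6, 2))
        y = np.array([1.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        res = loocv(X, y, TrainConfig(seed=0, epochs=20))
        assert res.single_class_folds == [0]


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1])) == 1.0

    def test_all_tied_scores(self):
        assert roc_auc(np.full(10, 0.4), np.r_[np.zeros(5), np.ones(5)]) == 0.5

    def test_random_scores_near_chance(self, rng):
        scores = rng.uniform(size=1000)
        labels = rng.integers(0, 2, 1000)
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_agrees_with_reference_implementation(self, rng):
        """In-repo rank-based AUC and threshold accuracy must match
        scikit-learn on 100 random prediction/label sets."""
        for _ in range(100):
            n = int(rng.integers(10, 60))
            scores = np.round(rng.uniform(size=n), 2)  # ties included
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert roc_auc(scores, labels) == pytest.approx(
                sklearn.metrics.roc_auc_score(labels, scores), rel=1e-12)
            assert accuracy(scores, labels) == pytest.approx(
                sklearn.metrics.accuracy_score(labels, scores >= 0.5), rel=1e-12)
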