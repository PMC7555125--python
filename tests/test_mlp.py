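"""From-scratch perceptron: forward oracle, gradients, early stopping."""

import math

import numpy as np
import pytest

from enose import MLPBinaryClassifier, TrainConfig, classify, forward, train
from enose.mlp import _loss_and_gradients, load_model, save_model


def _make_model(W1, b1, W2, b2):
    clf = MLPBinaryClassifier()
    clf.W1_, clf.b1_ = np.asarray(W1, float), np.asarray(b1, float)
    clf.W2_, clf.b2_ = np.asarray(W2, float), np.asarray(b2, float)
    clf.n_features_in_ = clf.W1_.shape[1]
    clf.classes_ = np.array([0, 1])
    return clf


def _two_loop_forward(W1, b1, W2, b2, x):
    """Independent scalar-loop evaluation (no linear-algebra shortcut)."""
    hidden = []
    for j in range(len(b1)):
        z = b1[j]
        for i in range(len(x)):
            z += W1[j][i] * x[i]
        hidden.append(1.0 / (1.0 + math.exp(-z)))
    z2 = b2[0]
    for j in range(len(hidden)):
        z2 += W2[0][j] * hidden[j]
    return 1.0 / (1.0 + math.exp(-z2))


class TestForward:
    def test_zero_model_outputs_half(self):
        clf = _make_model(np.zeros((4, 3)), np.zeros(4), np.zeros((1, 4)), np.zeros(1))
        assert forward(clf, np.array([1.0, -2.0, 3.0])) == 0.5

    def test_saturated_bias_outputs_one(self):
        clf = _make_model(np.zeros((4, 3)), np.zeros(4), np.zeros((1, 4)),
                          np.array([500.0]))
        assert forward(clf, np.zeros(3)) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_two_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nf, nh = 7, 5
        W1, b1 = rng.normal(size=(nh, nf)), rng.normal(size=nh)
        W2, b2 = rng.normal(size=(1, nh)), rng.normal(size=1)
        x = rng.normal(size=nf)
        clf = _make_model(W1, b1, W2, b2)
        expected = _two_loop_forward(W1.tolist(), b1.tolist(), W2.tolist(),
                                     b2.tolist(), x.tolist())
        assert forward(clf, x) == pytest.approx(expected, abs=1e-12)

    def test_non_finite_input_rejected(self):
        clf = _make_model(np.zeros((2, 2)), np.zeros(2), np.zeros((1, 2)), np.zeros(1))
        with pytest.raises(ValueError, match="finite"):
            forward(clf, np.array([1.0, np.nan]))


class TestClassify:
    def test_tie_goes_to_positive(self):
        clf = _make_model(np.zeros((2, 2)), np.zeros(2), np.zeros((1, 2)), np.zeros(1))
        assert classify(clf, np.ones(2), threshold=0.5) == 1

    def test_saturated_positive(self):
        clf = _make_model(np.zeros((2, 2)), np.zeros(2), np.zeros((1, 2)),
                          np.array([500.0]))
        assert classify(clf, np.ones(2)) == 1


class TestGradients:
    @pytest.mark.parametrize("loss", ["cross-entropy", "mse"])
    def test_backprop_matches_central_differences(self, loss):
        rng = np.random.default_rng(0)
        nf, nh, n = 10, 4, 7
        W1, b1 = rng.normal(size=(nh, nf)), rng.normal(size=nh)
        W2, b2 = rng.normal(size=(1, nh)), rng.normal(size=1)
        X = rng.normal(size=(n, nf))
        y = rng.integers(0, 2, n).astype(float)
        _, grads = _loss_and_gradients(W1, b1, W2, b2, X, y, loss)
        eps = 1e-5  # near cbrt(machine eps): balances truncation vs roundoff
        for key, arr in (("W1", W1), ("b1", b1), ("W2", W2), ("b2", b2)):
            numeric = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                arr[idx] += eps
                vp, _ = _loss_and_gradients(W1, b1, W2, b2, X, y, loss)
                arr[idx] -= 2 * eps
                vm, _ = _loss_and_gradients(W1, b1, W2, b2, X, y, loss)
                arr[idx] += eps
                numeric[idx] = (vp - vm) / (2 * eps)
            rel = np.abs(numeric - grads[key]) / (
                np.abs(numeric) + np.abs(grads[key]) + 1e-12
            )
            assert rel.max() < 1e-6, f"{loss}/{key}: rel err {rel.max():.2e}"


class TestTraining:
    @staticmethod
    def _separable(n=60, nf=10, seed=0, gap=3.0):
        rng = np.random.default_rng(seed)
        y = np.repeat([0.0, 1.0], n // 2)
        X = rng.normal(size=(n, nf)) + gap * y[:, None]
        idx = rng.permutation(n)
        return X[idx], y[idx]

    def test_separable_data_learned(self):
        X, y = self._separable()
        clf = train(X[:40], y[:40], X[40:], y[40:],
                    TrainConfig(max_epochs=2000, min_epochs=100, patience=300))
        assert clf.best_val_accuracy_ >= 0.95
        assert 0 < clf.best_epoch_ <= clf.n_epochs_ <= 2000

    def test_shuffled_labels_stay_at_chance(self):
        """Random labels: best held-out accuracy within the binomial band
        of the majority rate (no memorization leaks to held-out data)."""
        rng = np.random.default_rng(42)
        X = rng.normal(size=(60, 10))
        y = rng.permutation(np.repeat([0.0, 1.0], 30))
        cfg = TrainConfig(max_epochs=300, min_epochs=300, patience=10_000,
                          eval_every=100)
        clf = train(X[:35], y[:35], X[35:], y[35:], cfg)
        p0 = max(np.mean(y[35:]), 1 - np.mean(y[35:]))
        band = 1.96 * np.sqrt(p0 * (1 - p0) / 25)
        assert clf.best_val_accuracy_ <= p0 + band

    def test_determinism(self):
        X, y = self._separable(seed=3)
        cfg = TrainConfig(max_epochs=50, min_epochs=50, patience=100, seed=9)
        a = train(X[:40], y[:40], X[40:], y[40:], cfg)
        b = train(X[:40], y[:40], X[40:], y[40:], cfg)
        np.testing.assert_array_equal(a.W1_, b.W1_)
        np.testing.assert_array_equal(a.W2_, b.W2_)
        assert a.trace_.equals(b.trace_)

    def test_loss_monotone_at_small_learning_rate(self):
        X, y = self._separable(n=30, nf=5, seed=1)
        cfg = TrainConfig(learning_rate=1e-3, max_epochs=400, min_epochs=400,
                          patience=10_000, eval_every=1)
        clf = train(X[:20], y[:20], X[20:], y[20:], cfg)
        losses = clf.trace_["train_loss"].to_numpy()
        assert np.all(np.diff(losses) <= 1e-12)

    def test_best_snapshot_is_returned(self):
        """Returned parameters are frozen at the best held-out accuracy."""
        X, y = self._separable(seed=5)
        cfg = TrainConfig(max_epochs=500, min_epochs=100, patience=150)
        clf = train(X[:40], y[:40], X[40:], y[40:], cfg)
        pred = clf.predict(X[40:])
        acc = float(np.mean(pred == y[40:]))
        assert acc == pytest.approx(clf.best_val_accuracy_)

    def test_stop_epoch_within_bounds(self):
        X, y = self._separable(seed=7)
        clf = train(X[:40], y[:40], X[40:], y[40:],
                    TrainConfig(max_epochs=1000, min_epochs=200, patience=100))
        assert 200 <= clf.n_epochs_ <= 1000

    def test_hidden_width_is_twice_input(self):
        X, y = self._separable(nf=12, seed=2)
        clf = MLPBinaryClassifier(max_epochs=5, min_epochs=1, patience=100,
                                  random_state=0)
        clf.fit(X, y)
        assert clf.W1_.shape == (24, 12)
        assert clf.W2_.shape == (1, 24)

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            train(np.empty((0, 3)), np.empty(0), np.ones((2, 3)), np.ones(2))

    def test_config_validation(self):
        with pytest.raises(ValueError, match="learning_rate"):
            TrainConfig(learning_rate=0.0)
        with pytest.raises(ValueError, match="min_epochs"):
            TrainConfig(min_epochs=10, max_epochs=5)
        with pytest.raises(ValueError, match="loss"):
            TrainConfig(loss="hinge")


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path):
        X, y = TestTraining._separable(seed=4)
        cfg = TrainConfig(max_epochs=60, min_epochs=60, patience=100, seed=1)
        clf = train(X[:40], y[:40], X[40:], y[40:], cfg)
        path = tmp_path / "model.npz"
        save_model(clf, path)
        back = load_model(path)
        np.testing.assert_array_equal(clf.W1_, back.W1_)
        np.testing.assert_array_equal(clf.predict(X), back.predict(X))
        assert back.best_epoch_ == clf.best_epoch_
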