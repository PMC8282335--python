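"""Unit tests for the losses, the ADAM optimizer (against an independent
scalar oracle), the analytic gradients (against finite differences), and
the training loop."""

import math

import numpy as np
import pytest

from aptrans.network import NetConfig, init_params
from aptrans.training import (
    OptimizerState,
    TrainConfig,
    adam_update,
    cross_entropy,
    loss_and_gradients,
    mse_loss,
    total_loss,
    train,
)


class TestLosses:
    def test_mse_identical_is_zero(self):
        v = np.arange(10.0)
        assert mse_loss(v, v) == 0.0

    def test_mse_hand_value(self):
        assert mse_loss(np.array([1.0, 1.0]), np.array([0.0, 0.0])) == 1.0

    def test_mse_quadratic_homogeneity(self, rng):
        a, b = rng.normal(size=7), rng.normal(size=7)
        assert mse_loss(3 * a, 3 * b) == pytest.approx(9 * mse_loss(a, b))

    def test_mse_length_mismatch(self):
        with pytest.raises(ValueError):
            mse_loss(np.zeros(3), np.zeros(4))

    def test_cross_entropy_perfect_prediction_near_zero(self):
        assert cross_entropy(1, 1.0 - 1e-7) < 1e-6
        assert cross_entropy(0, 1e-7) < 1e-6

    def test_cross_entropy_half_is_ln2(self):
        assert cross_entropy(1, 0.5) == pytest.approx(math.log(2.0))

    def test_cross_entropy_symmetry(self, rng):
        for p in rng.uniform(0.01, 0.99, size=5):
            assert cross_entropy(0, p) == pytest.approx(cross_entropy(1, 1 - p))

    def test_cross_entropy_label_validation(self):
        with pytest.raises(ValueError):
            cross_entropy(2, 0.5)

    def test_total_loss_single_sample_reduction(self):
        y, t = np.ones(4), np.zeros(4)
        got = total_loss(y, t, [1], [0.5])
        assert got == pytest.approx(1.0 + math.log(2.0))

    def test_total_loss_two_sample_batch_mean(self):
        preds = np.array([[1.0, 1.0], [0.0, 0.0]])
        targs = np.zeros((2, 2))
        got = total_loss(preds, targs, [1, 0], [0.5, 0.5])
        assert got == pytest.approx(0.5 + math.log(2.0))

    def test_total_loss_empty_batch(self):
        with pytest.raises(ValueError):
            total_loss(np.zeros((0, 3)), np.zeros((0, 3)), [], [])

    def test_perfect_predictions_zero_loss(self):
        y = np.ones((2, 3))
        assert total_loss(y, y, [1, 1], [1 - 1e-7] * 2) < 1e-6


def _adam_oracle(theta0, grads, alpha=0.001, b1=0.9, b2=0.999, eps=1e-8):
    """Independent scalar ADAM: plain floats, textbook recursion."""
    theta, m, v = float(theta0), 0.0, 0.0
    for t, g in enumerate(grads, start=1):
        m = (1 - b1) * g + b1 * m
        v = (1 - b2) * g * g + b2 * v
        mhat = m / (1 - b1 ** t)
        vhat = v / (1 - b2 ** t)
        theta = theta - alpha * mhat / (math.sqrt(vhat) + eps)
    return theta


class TestAdam:
    def test_zero_gradient_leaves_everything_unchanged(self):
        params = {"w": np.array([1.0, -2.0])}
        state = OptimizerState.for_params(params)
        adam_update(params, {"w": np.zeros(2)}, state, TrainConfig())
        assert np.array_equal(params["w"], [1.0, -2.0])
        assert np.array_equal(state.m["w"], np.zeros(2))
        assert np.array_equal(state.v["w"], np.zeros(2))
        assert state.t == 1

    def test_first_step_closed_form(self):
        # theta0=1, g=4: mhat=4, vhat=16, theta1 = 1 - 0.001*4/(4+1e-8)
        params = {"w": np.array([1.0])}
        state = OptimizerState.for_params(params)
        adam_update(params, {"w": np.array([4.0])}, state, TrainConfig())
        expected = 1.0 - 0.001 * 4.0 / (4.0 + 1e-8)
        assert params["w"][0] == pytest.approx(expected, abs=1e-15)

    def test_hundred_random_steps_match_scalar_oracle(self, rng):
        grads = rng.normal(size=100)
        params = {"w": np.array([0.7])}
        state = OptimizerState.for_params(params)
        cfg = TrainConfig()
        for g in grads:
            adam_update(params, {"w": np.array([g])}, state, cfg)
        want = _adam_oracle(0.7, grads)
        assert abs(params["w"][0] - want) < 1e-12

    def test_constant_gradient_step_approaches_alpha(self):
        params = {"w": np.array([0.0])}
        state = OptimizerState.for_params(params)
        cfg = TrainConfig()
        prev = 0.0
        for _ in range(2000):
            prev = params["w"][0]
            adam_update(params, {"w": np.array([2.5])}, state, cfg)
        # sign-descent limit: |step| -> alpha
        assert abs(prev - params["w"][0]) == pytest.approx(cfg.alpha, rel=1e-3)

    def test_nan_gradient_names_parameter(self):
        params = {"w": np.array([1.0])}
        state = OptimizerState.for_params(params)
        with pytest.raises(FloatingPointError, match="w"):
            adam_update(params, {"w": np.array([np.nan])}, state, TrainConfig())


def gradient_check(include_classifier=True, seed=3, n_per_param=5):
    """Analytic vs central finite-difference gradients on a tiny network.

    Returns the worst relative error over sampled coordinates."""
    cfg = NetConfig(window=7, hidden_size=4, trans_hidden=5, clf_hidden=3,
                    dropout=0.0, include_classifier=include_classifier)
    params = init_params(cfg, seed=seed)
    rng = np.random.default_rng(0)
    x = rng.normal(size=(3, 7)) * 0.5
    y = rng.normal(size=(3, 7)) * 0.5
    lab = np.array([0, 1, 1]) if include_classifier else None
    _, grads = loss_and_gradients(params, x, y, lab, training=False)
    flat = params.flat()
    eps = 1e-6
    worst = 0.0
    pick = np.random.default_rng(1)
    for name, arr in flat.items():
        for i in pick.choice(arr.size, size=min(n_per_param, arr.size),
                             replace=False):
            ix = tuple(np.unravel_index(i, arr.shape))
            old = arr[ix]
            arr[ix] = old + eps
            lp = loss_and_gradients(params, x, y, lab, training=False)[0]["total"]
            arr[ix] = old - eps
            lm = loss_and_gradients(params, x, y, lab, training=False)[0]["total"]
            arr[ix] = old
            num = (lp - lm) / (2 * eps)
            ana = grads[name][ix]
            worst = max(worst, abs(num - ana) / max(1e-8, abs(num) + abs(ana)))
    return worst


class TestGradients:
    def test_analytic_matches_finite_differences(self):
        assert gradient_check(include_classifier=True) < 1e-4

    def test_translation_only_gradients(self):
        assert gradient_check(include_classifier=False) < 1e-4


def _toy_data(rng, n=8, window=31):
    X = rng.normal(size=(n, window)) * 0.3
    Y = np.sin(np.linspace(0, 3, window))[None] * rng.uniform(0.2, 0.9, (n, 1))
    L = (np.arange(n) % 2)
    return dict(X_train=X, Y_train=Y, labels_train=L,
                X_val=X, Y_val=Y, labels_val=L)


class TestTrainLoop:
    def test_overfits_small_dataset(self, rng):
        data = _toy_data(rng, n=4)
        cfg = NetConfig(window=31, hidden_size=8, trans_hidden=16,
                        clf_hidden=8, dropout=0.0)
        params = init_params(cfg, seed=0)
        best, hist = train(data, params,
                           TrainConfig(epochs=500, batch_size=4,
                                       patience=500, seed=0))
        assert hist[-1]["train_mse"] < 1e-3

    def test_same_seed_identical_history(self, rng):
        data = _toy_data(rng)
        cfg = NetConfig(window=31, hidden_size=6, trans_hidden=8,
                        clf_hidden=4, dropout=0.2)
        runs = []
        for _ in range(2):
            params = init_params(cfg, seed=1)
            _, hist = train(data, params,
                            TrainConfig(epochs=5, batch_size=4, seed=9))
            runs.append(hist)
        assert runs[0] == runs[1]

    def test_training_loss_decreases_over_first_epochs(self, rng):
        data = _toy_data(rng, n=16)
        cfg = NetConfig(window=31, hidden_size=8, trans_hidden=12,
                        clf_hidden=6, dropout=0.0)
        params = init_params(cfg, seed=2)
        _, hist = train(data, params,
                        TrainConfig(epochs=10, batch_size=8,
                                    patience=10, seed=0))
        assert hist[-1]["train_total"] < hist[0]["train_total"]

    def test_early_stopping_respects_patience(self, rng):
        data = _toy_data(rng, n=6)
        cfg = NetConfig(window=31, hidden_size=4, trans_hidden=6,
                        clf_hidden=3, dropout=0.0)
        params = init_params(cfg, seed=0)
        _, hist = train(data, params,
                        TrainConfig(epochs=300, batch_size=6, patience=3,
                                    min_delta=1e-3, seed=0))
        assert len(hist) < 300
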