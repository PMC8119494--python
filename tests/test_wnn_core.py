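"""Wavelet-network core: activation identities, forward pass, gradients,
initialization, training dynamics, model selection, MLP baseline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from gaitwnn.wnn_core import (
    MLPParameters,
    TrainingConfig,
    TrainingDivergence,
    WNNParameters,
    cost,
    forward,
    gradients,
    init_mlp_params,
    init_params,
    mexican_hat,
    mexican_hat_deriv,
    mlp_baseline,
    params_from_json,
    params_to_json,
    prediction_risk,
    select_hidden_nodes,
    train,
    wavelon_activation,
    wavelon_input,
)


def random_wnn(rng, k=3, i=2, j=2):
    return WNNParameters(
        w_direct=rng.normal(0, 0.5, (k, j)),
        w_out=rng.normal(0, 0.5, (i, j)),
        xi=rng.normal(0, 0.5, (k, i)),
        sigma=rng.uniform(0.3, 1.0, (k, i)),
        bias=rng.normal(0, 0.5, j),
    )


def naive_forward(params: WNNParameters, xv: np.ndarray) -> np.ndarray:
    """Triple-loop oracle for the network output."""
    k_n, j_n = params.w_direct.shape
    i_n = params.w_out.shape[0]
    out = np.zeros(j_n)
    for j in range(j_n):
        acc = params.bias[j]
        for i in range(i_n):
            prod = 1.0
            for k in range(k_n):
                z = (xv[k] - params.xi[k, i]) / params.sigma[k, i]
                prod *= mexican_hat(z)
            acc += prod * params.w_out[i, j]
        for k in range(k_n):
            acc += xv[k] * params.w_direct[k, j]
        out[j] = acc
    return out


class TestMexicanHat:
    def test_fixed_values(self):
        assert mexican_hat(0.0) == 1.0
        assert mexican_hat(1.0) == 0.0
        assert mexican_hat(-1.0) == 0.0
        assert mexican_hat(2.0) == pytest.approx(-3 * np.exp(-2.0))

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(z=st.floats(min_value=-50, max_value=50))
    def test_even_symmetry(self, z):
        assert mexican_hat(z) == pytest.approx(mexican_hat(-z), rel=1e-12, abs=1e-300)

    def test_zero_mean_wave(self):
        integral, _ = quad(mexican_hat, -8, 8)
        assert integral == pytest.approx(0.0, abs=1e-6)

    def test_derivative_matches_finite_difference(self):
        z = np.linspace(-4, 4, 33)
        h = 1e-6
        fd = (mexican_hat(z + h) - mexican_hat(z - h)) / (2 * h)
        np.testing.assert_allclose(mexican_hat_deriv(z), fd, atol=1e-8)


class TestWavelonPrimitives:
    @pytest.mark.parametrize(
        "x, xi, sigma, expected",
        [(0.7, 0.7, 0.5, 0.0), (1.2, 0.7, 0.5, 1.0), (0.2, 0.7, 0.01, -50.0)],
    )
    def test_wavelon_input(self, x, xi, sigma, expected):
        assert wavelon_input(x, xi, sigma) == pytest.approx(expected)

    def test_zero_dilation_rejected(self):
        with pytest.raises(ValueError):
            wavelon_input(1.0, 0.0, 0.0)

    def test_activation_is_product_of_scalar_hats(self):
        x = np.full(22, 0.5)
        act = wavelon_activation(x, np.zeros(22), np.ones(22))
        assert act == pytest.approx(mexican_hat(0.5) ** 22)
        assert wavelon_activation(np.zeros(3), np.zeros(3), np.ones(3)) == 1.0
        # any factor at a wavelet zero annihilates the product
        assert wavelon_activation(np.array([1.0, 0.3]), np.zeros(2), np.ones(2)) == 0.0


class TestForward:
    def test_bias_passthrough(self):
        p = WNNParameters(
            w_direct=np.zeros((3, 2)), w_out=np.zeros((2, 2)),
            xi=np.zeros((3, 2)), sigma=np.ones((3, 2)), bias=np.array([4.0, -1.0]),
        )
        out = forward(p, np.array([0.3, -0.2, 0.9]))
        np.testing.assert_allclose(out, [4.0, -1.0])

    def test_linear_path(self):
        p = WNNParameters(
            w_direct=np.zeros((3, 2)), w_out=np.zeros((2, 2)),
            xi=np.zeros((3, 2)), sigma=np.ones((3, 2)), bias=np.zeros(2),
        )
        p.w_direct[1, 0] = 1.0
        x = np.array([0.5, 0.7, -0.3])
        assert forward(p, x)[0] == pytest.approx(0.7)

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(20):
            p = random_wnn(rng)
            x = rng.normal(size=3)
            np.testing.assert_allclose(forward(p, x), naive_forward(p, x), atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            forward(random_wnn(rng), np.zeros(5))


class TestCost:
    def test_values(self):
        y = np.array([[1.0, 2.0]])
        assert cost(y, y) == 0.0
        assert cost(np.array([[2.0]]), np.array([[0.0]])) == 4.0
        # per-sample squared errors 1 and 3 -> mean 2
        assert cost(np.array([[1.0, 3.0]]), np.array([[0.0, 3.0 - np.sqrt(3)]])) == pytest.approx(2.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cost(np.zeros((2, 3)), np.zeros((3, 2)))


class TestGradients:
    def test_zero_at_perfect_fit(self):
        p = WNNParameters(
            w_direct=np.zeros((2, 1)), w_out=np.zeros((1, 1)),
            xi=np.zeros((2, 1)), sigma=np.ones((2, 1)), bias=np.array([2.0]),
        )
        x = np.random.default_rng(0).normal(size=(2, 6))
        y = np.full((1, 6), 2.0)  # network already outputs exactly 2
        g = gradients(p, x, y)
        for name in ("w_direct", "w_out", "xi", "sigma", "bias"):
            np.testing.assert_allclose(g[name], 0.0, atol=1e-14)

    def test_bias_gradient_is_twice_mean_residual(self, rng):
        p = random_wnn(rng)
        x = rng.normal(size=(3, 9))
        y = rng.normal(size=(2, 9))
        resid = forward(p, x) - y
        np.testing.assert_allclose(
            gradients(p, x, y)["bias"], 2.0 * resid.mean(axis=1), rtol=1e-12
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_central_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        p = random_wnn(rng, k=3, i=2, j=2)
        x = rng.normal(size=(3, 7))
        y = rng.normal(size=(2, 7))
        g = gradients(p, x, y)
        h = 1e-6
        for name, arr in p.arrays().items():
            for idx in np.ndindex(arr.shape):
                orig = arr[idx]
                arr[idx] = orig + h
                cp = cost(y, forward(p, x))
                arr[idx] = orig - h
                cm = cost(y, forward(p, x))
                arr[idx] = orig
                fd = (cp - cm) / (2 * h)
                assert abs(fd - g[name][idx]) < 1e-5 * max(1.0, abs(fd)), name


class TestInit:
    def test_translations_at_input_midpoints(self, rng):
        x = rng.uniform(0.2, 1.2, size=(1, 50))
        x[0, 0], x[0, 1] = 0.2, 1.2  # pin the extremes
        p = init_params(x, np.full((1, 50), 5.0), n_hidden=4, seed=0)
        np.testing.assert_allclose(p.xi, 0.7)
        np.testing.assert_allclose(p.bias, [5.0])
        np.testing.assert_allclose(p.sigma, 0.25 * 1.0)

    def test_dilation_cap_and_floor(self, rng):
        x = np.vstack([rng.uniform(0, 10, 30), np.full(30, 1.0)])
        with pytest.warns(RuntimeWarning, match="constant"):
            p = init_params(x, rng.normal(size=(2, 30)), n_hidden=2, seed=0)
        assert np.all(p.sigma[0] <= 1.0)
        assert np.all(p.sigma[1] == pytest.approx(1e-3))

    def test_deterministic_under_seed(self, rng):
        x = rng.uniform(size=(4, 20))
        y = rng.normal(size=(3, 20))
        a = init_params(x, y, 5, seed=9)
        b = init_params(x, y, 5, seed=9)
        for k, v in a.arrays().items():
            np.testing.assert_array_equal(v, b.arrays()[k])


class TestTraining:
    def test_zero_learning_rate_keeps_params(self, rng):
        x = rng.uniform(size=(3, 20))
        y = rng.normal(size=(2, 20))
        p0 = init_params(x, y, 2, seed=0)
        cfg = TrainingConfig(epochs=50, learning_rate=0.0, momentum=0.0)
        fitted, trace = train(p0, x, y, cfg)
        for k, v in fitted.arrays().items():
            np.testing.assert_array_equal(v, p0.arrays()[k])
        assert len(trace.costs) == 50
        assert len(set(trace.costs)) == 1
        assert trace.stop_reason == "epoch_cap"

    def test_cost_floor_stops_at_first_epoch(self, rng):
        x = rng.uniform(size=(3, 20))
        y = rng.normal(size=(2, 20))
        p0 = init_params(x, y, 2, seed=0)
        initial = cost(y, forward(p0, x))
        cfg = TrainingConfig(epochs=50, cost_floor=initial * 2)
        _, trace = train(p0, x, y, cfg)
        assert trace.stop_reason == "cost_floor"
        assert len(trace.costs) == 1

    def test_linear_map_is_learned(self, rng):
        x = rng.uniform(0, 1, size=(3, 60))
        w = rng.normal(size=(3, 2))
        y = w.T @ x + 0.5
        p0 = init_params(x, y, 2, seed=0)
        cfg = TrainingConfig(epochs=50, learning_rate=0.15, momentum=0.8)
        fitted, trace = train(p0, x, y, cfg)
        assert trace.costs[-1] < trace.costs[0]
        assert cost(y, forward(fitted, x)) < 1e-3

    def test_cost_monotone_without_momentum_at_small_lr(self, rng):
        x = rng.uniform(size=(3, 30))
        y = rng.normal(size=(2, 30))
        p0 = init_params(x, y, 3, seed=0)
        cfg = TrainingConfig(epochs=40, learning_rate=1e-3, momentum=0.0)
        _, trace = train(p0, x, y, cfg)
        assert np.all(np.diff(trace.costs) <= 1e-12)

    def test_divergence_raises_with_trace(self, rng):
        x = rng.uniform(size=(2, 10))
        y = 1e3 * rng.normal(size=(2, 10))
        p0 = init_params(x, y, 2, seed=0)
        cfg = TrainingConfig(epochs=200, learning_rate=50.0, momentum=0.9)
        with pytest.raises(TrainingDivergence) as err:
            train(p0, x, y, cfg)
        assert len(err.value.trace.costs) >= 1


class TestPredictionRiskAndSelection:
    def test_risk_values(self, rng):
        p = random_wnn(rng, k=2, i=1, j=66)
        x = rng.uniform(size=(2, 5))
        y = forward(p, x)
        assert prediction_risk(p, x, y) == 0.0
        assert prediction_risk(p, x, y + 1.0) == pytest.approx(66.0)

    def test_risk_equals_cost_form(self, rng):
        p = random_wnn(rng)
        x = rng.uniform(size=(3, 8))
        y = rng.normal(size=(2, 8))
        assert prediction_risk(p, x, y) == cost(y, forward(p, x))

    def test_empty_test_set_rejected(self, rng):
        with pytest.raises(ValueError):
            prediction_risk(random_wnn(rng), np.zeros((3, 0)), np.zeros((2, 0)))

    def test_single_candidate(self, rng):
        x = rng.uniform(size=(3, 40))
        y = rng.normal(size=(2, 40))
        cfg = TrainingConfig(epochs=5)
        assert select_hidden_nodes(x, y, [5], cfg) == 5

    def test_selection_deterministic(self, rng):
        x = rng.uniform(size=(3, 60))
        y = np.sin(6 * x[:2]) + 0.1 * rng.normal(size=(2, 60))
        cfg = TrainingConfig(epochs=30, learning_rate=0.05, seed=4)
        a = select_hidden_nodes(x, y, [1, 2, 4], cfg)
        b = select_hidden_nodes(x, y, [1, 2, 4], cfg)
        assert a == b


class TestMLPBaseline:
    def test_sigmoid_midpoint_and_bias_passthrough(self):
        p = MLPParameters(
            w_in=np.zeros((3, 2)), b_hidden=np.zeros(2),
            w_out=np.zeros((2, 1)), bias=np.array([3.0]),
        )
        out = forward(p, np.array([1.0, -2.0, 0.5]))
        np.testing.assert_allclose(out, [3.0])

    def test_gradients_match_finite_differences(self, rng):
        p = init_mlp_params(rng.uniform(size=(3, 1)), rng.normal(size=(2, 1)), 2, seed=0)
        x = rng.uniform(size=(3, 7))
        y = rng.normal(size=(2, 7))
        g = gradients(p, x, y)
        h = 1e-6
        for name, arr in p.arrays().items():
            for idx in np.ndindex(arr.shape):
                orig = arr[idx]
                arr[idx] = orig + h
                cp = cost(y, forward(p, x))
                arr[idx] = orig - h
                cm = cost(y, forward(p, x))
                arr[idx] = orig
                fd = (cp - cm) / (2 * h)
                assert abs(fd - g[name][idx]) < 1e-5 * max(1.0, abs(fd))

    def test_matched_budget_run_completes(self, rng):
        x = rng.uniform(size=(5, 40))
        y = rng.normal(size=(3, 40))
        cfg = TrainingConfig(epochs=50, n_hidden=5)
        fitted, trace = mlp_baseline(x, y, cfg)
        assert len(trace.costs) == 50
        assert np.isfinite(trace.costs[-1])


class TestSerialization:
    def test_wnn_roundtrip(self, rng):
        p = random_wnn(rng)
        q = params_from_json(params_to_json(p))
        for k, v in p.arrays().items():
            np.testing.assert_array_equal(v, q.arrays()[k])
        assert isinstance(q, WNNParameters)

    def test_mlp_roundtrip(self, rng):
        p = init_mlp_params(rng.uniform(size=(3, 5)), rng.normal(size=(2, 5)), 4)
        q = params_from_json(params_to_json(p))
        assert isinstance(q, MLPParameters)
        np.testing.assert_array_equal(p.w_in, q.w_in)
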