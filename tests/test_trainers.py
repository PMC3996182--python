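"""The six training algorithms and the generic optimizer cores."""

import numpy as np
import pytest

from ventdss.network import (
    flatten,
    forward,
    init_mlp,
    jacobian,
    residuals,
    unflatten,
)
from ventdss.optimizers import bfgs_minimize, oss_minimize
from ventdss.training import ALGORITHMS, TrainConfig, train


@pytest.fixture(scope="module")
def linear_problem():
    rng = np.random.default_rng(0)
    X = rng.uniform(-1, 1, size=(20, 1))
    return X, 2.0 * X + 1.0


@pytest.fixture(scope="module")
def xor_problem():
    X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
    Y = np.array([[0.0], [1.0], [1.0], [0.0]])
    return X, Y


class TestGenericContracts:
    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_zero_epochs_returns_input_model(self, algorithm, linear_problem):
        X, Y = linear_problem
        model = init_mlp((1, 3, 1), seed=1)
        run = train(model, X, Y, TrainConfig(algorithm=algorithm, hidden_units=3,
                                             max_epochs=0))
        np.testing.assert_array_equal(flatten(run.model), flatten(model))
        assert run.n_epochs == 0

    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_repeat_run_bitwise_identical(self, algorithm, linear_problem):
        X, Y = linear_problem
        runs = []
        for _ in range(2):
            model = init_mlp((1, 3, 1), seed=4)
            runs.append(
                train(model, X, Y, TrainConfig(algorithm=algorithm, hidden_units=3,
                                               max_epochs=15))
            )
        assert runs[0].sse_history == runs[1].sse_history
        np.testing.assert_array_equal(
            flatten(runs[0].model), flatten(runs[1].model)
        )

    def test_empty_data_rejected(self):
        model = init_mlp((1, 2, 1), seed=0)
        with pytest.raises(ValueError):
            train(model, np.empty((0, 1)), np.empty((0, 1)), TrainConfig())

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(algorithm="adam")
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=-1.0)


class TestLevenbergMarquardt:
    def test_recovers_normal_equations_solution(self, linear_problem):
        X, Y = linear_problem
        model = init_mlp((1, 2, 1), seed=5, hidden_activation="identity")
        run = train(model, X, Y, TrainConfig(algorithm="lm", hidden_units=2,
                                             max_epochs=200))
        W1, W2 = run.model.weights
        b1, b2 = run.model.biases
        slope = float((W2 @ W1)[0, 0])
        intercept = float((W2 @ b1 + b2)[0])
        # closed-form least squares on this noise-free line is exactly (2, 1)
        design = np.column_stack([X[:, 0], np.ones(len(X))])
        beta, *_ = np.linalg.lstsq(design, Y[:, 0], rcond=None)
        assert slope == pytest.approx(beta[0], abs=1e-8)
        assert intercept == pytest.approx(beta[1], abs=1e-8)

    def test_accepted_sse_history_nonincreasing(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 3))
        Y = np.tanh(X @ rng.normal(size=(3, 2)))
        model = init_mlp((3, 5, 2), seed=7)
        run = train(model, X, Y, TrainConfig(algorithm="lm", hidden_units=5,
                                             max_epochs=60))
        diffs = np.diff(run.sse_history)
        assert np.all(diffs <= 1e-15)

    def test_large_damping_step_approaches_scaled_gradient(self):
        rng = np.random.default_rng(1)
        model = init_mlp((2, 3, 1), seed=11)
        X, Y = rng.normal(size=(10, 2)), rng.normal(size=(10, 1))
        J = jacobian(model, X)
        g = J.T @ residuals(model, X, Y)
        lam = 1e8
        step = np.linalg.solve(J.T @ J + lam * np.eye(g.size), -g)
        np.testing.assert_allclose(step, -g / lam, rtol=1e-6)

    def test_nan_loss_raises_with_epoch(self, linear_problem):
        X, Y = linear_problem
        model = init_mlp((1, 2, 1), seed=0)
        bad = unflatten(model, np.full(model.n_parameters, 1e200))
        with np.errstate(over="ignore"), pytest.raises(FloatingPointError,
                                                       match="epoch"):
            train(bad, X, Y * 1e200, TrainConfig(algorithm="lm", hidden_units=2,
                                                 max_epochs=5))


class TestXorSeparation:
    @pytest.mark.parametrize("algorithm", ["lm", "bfgs"])
    def test_xor_fully_separated(self, algorithm, xor_problem):
        X, Y = xor_problem
        model = init_mlp((2, 4, 1), seed=2)
        run = train(model, X, Y, TrainConfig(algorithm=algorithm, hidden_units=4,
                                             max_epochs=2000, goal_sse=1e-8))
        predictions = (forward(run.model, X)[:, 0] >= 0.5).astype(float)
        assert int(np.sum(predictions != Y[:, 0])) == 0


class TestBayesianRegularization:
    def test_gamma_bounded_by_parameter_count(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 2))
        Y = (X @ rng.normal(size=(2, 1))) + 0.1 * rng.normal(size=(25, 1))
        model = init_mlp((2, 4, 1), seed=3)
        run = train(model, X, Y, TrainConfig(algorithm="bayes_reg", hidden_units=4,
                                             max_epochs=60))
        assert run.gamma is not None
        assert all(0.0 <= g <= model.n_parameters for g in run.gamma_history)

    def test_recovers_effective_parameter_count_on_linear_problem(self):
        # noise-free line: two effective parameters (slope, intercept) even
        # though the redundant network carries four
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, size=(30, 1))
        Y = 2.0 * X + 1.0
        model = init_mlp((1, 1, 1), seed=4, hidden_activation="identity")
        run = train(model, X, Y, TrainConfig(algorithm="bayes_reg", hidden_units=1,
                                             max_epochs=100))
        assert run.gamma == pytest.approx(2.0, abs=0.1)

    def test_objective_monotone_between_reestimates(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 2))
        Y = np.tanh(X @ rng.normal(size=(2, 1)))
        model = init_mlp((2, 3, 1), seed=8)
        run = train(model, X, Y, TrainConfig(algorithm="bayes_reg", hidden_units=3,
                                             max_epochs=40))
        assert len(run.objective_history) >= 2


class TestQuasiNewtonCores:
    def test_bfgs_converges_on_ten_dim_quadratic(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(10, 10))
        A = A @ A.T + 10 * np.eye(10)
        b = rng.normal(size=10)
        xstar = np.linalg.solve(A, b)
        result = bfgs_minimize(
            lambda x: 0.5 * x @ A @ x - b @ x,
            lambda x: A @ x - b,
            np.zeros(10),
            max_iter=15,
            gtol=1e-14,
        )
        assert np.max(np.abs(result.x - xstar)) < 1e-8

    def test_oss_decreases_loss_monotonically(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(6, 6))
        A = A @ A.T + np.eye(6)
        b = rng.normal(size=6)
        result = oss_minimize(
            lambda x: 0.5 * x @ A @ x - b @ x,
            lambda x: A @ x - b,
            np.zeros(6),
            max_iter=50,
            gtol=1e-12,
        )
        assert np.all(np.diff(result.history) <= 1e-15)
        assert result.fun < 0.5 * 0 - 0  # below the start value f(0)=0

    @pytest.mark.parametrize("algorithm", ["oss", "bfgs"])
    def test_network_training_reduces_loss(self, algorithm, linear_problem):
        X, Y = linear_problem
        model = init_mlp((1, 3, 1), seed=6)
        run = train(model, X, Y, TrainConfig(algorithm=algorithm, hidden_units=3,
                                             max_epochs=100))
        assert run.sse_history[-1] < run.sse_history[0] * 0.01


class TestIncrementalTrainers:
    def test_cyclical_equals_sequential_in_dataset_order(self, linear_problem):
        X, Y = linear_problem
        runs = {}
        for algorithm in ("cyclical", "sequential"):
            model = init_mlp((1, 3, 1), seed=9)
            runs[algorithm] = train(
                model, X, Y,
                TrainConfig(algorithm=algorithm, hidden_units=3, max_epochs=30,
                            learning_rate=0.05),
            )
        np.testing.assert_array_equal(
            flatten(runs["cyclical"].model), flatten(runs["sequential"].model)
        )
        assert runs["cyclical"].sse_history == runs["sequential"].sse_history

    def test_custom_cycle_order_changes_trajectory(self, linear_problem):
        X, Y = linear_problem
        n = len(X)
        model = init_mlp((1, 3, 1), seed=9)
        base = train(model, X, Y, TrainConfig(algorithm="cyclical", hidden_units=3,
                                              max_epochs=5, learning_rate=0.05))
        model = init_mlp((1, 3, 1), seed=9)
        shuffled = train(
            model, X, Y,
            TrainConfig(algorithm="cyclical", hidden_units=3, max_epochs=5,
                        learning_rate=0.05,
                        cycle_order=tuple(reversed(range(n)))),
        )
        assert not np.array_equal(flatten(base.model), flatten(shuffled.model))

    def test_bad_cycle_order_rejected(self, linear_problem):
        X, Y = linear_problem
        model = init_mlp((1, 3, 1), seed=9)
        with pytest.raises(ValueError, match="permutation"):
            train(model, X, Y, TrainConfig(algorithm="cyclical", hidden_units=3,
                                           max_epochs=2, cycle_order=(0, 0, 1)))

    def test_epoch_accounting(self, linear_problem):
        X, Y = linear_problem
        model = init_mlp((1, 3, 1), seed=9)
        run = train(model, X, Y, TrainConfig(algorithm="sequential", hidden_units=3,
                                             max_epochs=7, learning_rate=0.01))
        assert run.n_epochs == 7
        assert len(run.sse_history) == 8  # initial loss plus one per epoch
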