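"""The six network training regimes and their shared configuration.

Four batch algorithms — Levenberg–Marquardt (``lm``), Bayesian regularization
(``bayes_reg``), one-step secant (``oss``) and BFGS quasi-Newton (``bfgs``) —
and two incremental per-sample schemes — cyclical-order (``cyclical``) and
sequential-order (``sequential``) weight/bias updates.  All minimize the
sum-of-squared-error loss of :mod:`ventdss.network`; Bayesian regularization
adds the evidence-framework weight penalty and re-estimates its
hyperparameters from the data.

Every trainer is deterministic given (initial model, data, config): the only
randomness in a training run is the seeded weight initialization done by the
caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .network import (
    MLPModel,
    flatten,
    gradient,
    jacobian,
    residuals,
    sse_loss,
    unflatten,
)
from .optimizers import bfgs_minimize, oss_minimize

logger = logging.getLogger(__name__)

ALGORITHMS = ("lm", "bayes_reg", "oss", "bfgs", "cyclical", "sequential")

STOP_REASONS = ("goal", "gradient", "max_epochs", "lambda_overflow")

LAMBDA_MAX = 1e10
HYPER_CAP = 1e10  # cap on evidence-framework alpha/beta re-estimates


@dataclass(frozen=True)
class TrainConfig:
    """One training execution's algorithm choice and hyperparameters.

    ``learning_rate`` applies to the incremental trainers only;
    ``lm_lambda_init``/``lm_lambda_factor`` to ``lm`` and ``bayes_reg``.
    ``cycle_order`` fixes the presentation cycle of the cyclical trainer
    (defaults to dataset order).
    """

    algorithm: str = "lm"
    hidden_units: int = 30
    max_epochs: int = 200
    goal_sse: float = 0.0
    gradient_tolerance: float = 1e-10
    learning_rate: float = 0.01
    lm_lambda_init: float = 1e-3
    lm_lambda_factor: float = 10.0
    br_max_outer: int = 50
    seed: int = 0
    cycle_order: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.hidden_units <= 0:
            raise ValueError("hidden_units must be positive")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be nonnegative")
        if self.goal_sse < 0 or self.gradient_tolerance < 0:
            raise ValueError("tolerances must be nonnegative")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.lm_lambda_init <= 0 or self.lm_lambda_factor <= 1:
            raise ValueError("lm damping parameters must be positive (factor > 1)")


@dataclass
class TrainRun:
    """Result of one training execution.

    ``sse_history`` holds the loss after every epoch, the initial loss first.
    For ``bayes_reg``, ``alpha``/``beta``/``gamma`` carry the final evidence
    hyperparameters and the effective number of parameters.
    """

    model: MLPModel
    sse_history: list[float]
    stop_reason: str
    n_epochs: int
    alpha: float | None = None
    beta: float | None = None
    gamma: float | None = None
    gamma_history: list[float] = field(default_factory=list)
    objective_history: list[float] = field(default_factory=list)


def _check_finite(value: float, epoch: int) -> None:
    if not np.isfinite(value):
        raise FloatingPointError(f"non-finite loss at epoch {epoch}")


# ---------------------------------------------------------------------------
# Levenberg–Marquardt


def _train_lm(model: MLPModel, X, Y, config: TrainConfig) -> TrainRun:
    theta = flatten(model)
    current = unflatten(model, theta)
    lam = config.lm_lambda_init
    sse = sse_loss(current, X, Y)
    history = [sse]
    stop = "max_epochs"
    epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        if sse <= config.goal_sse:
            stop = "goal"
            epoch -= 1
            break
        r = residuals(current, X, Y)
        J = jacobian(current, X)
        g = J.T @ r
        if np.max(np.abs(g)) < config.gradient_tolerance:
            stop = "gradient"
            epoch -= 1
            break
        JTJ = J.T @ J
        accepted = False
        while lam <= LAMBDA_MAX:
            try:
                step = np.linalg.solve(
                    JTJ + lam * np.eye(theta.size), -g
                )
            except np.linalg.LinAlgError:
                lam *= config.lm_lambda_factor
                continue
            candidate = unflatten(current, theta + step)
            new_sse = sse_loss(candidate, X, Y)
            _check_finite(new_sse, epoch)
            if new_sse < sse:
                theta = theta + step
                current = candidate
                sse = new_sse
                lam = max(lam / config.lm_lambda_factor, 1e-20)
                accepted = True
                break
            lam *= config.lm_lambda_factor
        if not accepted:
            stop = "lambda_overflow"
            epoch -= 1
            break
        history.append(sse)
        logger.info("lm epoch %d sse=%.6g lambda=%.3g", epoch, sse, lam)
    else:
        if sse <= config.goal_sse:
            stop = "goal"
    return TrainRun(current, history, stop, len(history) - 1)


# ---------------------------------------------------------------------------
# Bayesian regularization (evidence framework)


def _train_bayes_reg(model: MLPModel, X, Y, config: TrainConfig) -> TrainRun:
    theta = flatten(model)
    current = unflatten(model, theta)
    n_params = theta.size
    n_resid = residuals(current, X, Y).size
    alpha, beta = 0.0, 1.0
    lam = config.lm_lambda_init
    sse = sse_loss(current, X, Y)  # E_D = 1/2 sum r^2
    e_w = 0.5 * float(theta @ theta)
    objective = beta * sse + alpha * e_w
    history = [sse]
    obj_history = [objective]
    gamma = float(n_params)
    gamma_history: list[float] = []
    stop = "max_epochs"
    epochs_done = 0
    outer = 0
    while epochs_done < config.max_epochs and outer < config.br_max_outer:
        outer += 1
        # inner: damped Gauss–Newton steps on the fixed-(alpha, beta) objective
        inner_accepted = False
        while epochs_done < config.max_epochs:
            if sse <= config.goal_sse:
                stop = "goal"
                break
            r = residuals(current, X, Y)
            J = jacobian(current, X)
            g = beta * (J.T @ r) + alpha * theta
            if np.max(np.abs(g)) < config.gradient_tolerance:
                stop = "gradient"
                break
            H = beta * (J.T @ J) + alpha * np.eye(n_params)
            accepted = False
            while lam <= LAMBDA_MAX:
                try:
                    step = np.linalg.solve(H + lam * np.eye(n_params), -g)
                except np.linalg.LinAlgError:
                    lam *= config.lm_lambda_factor
                    continue
                cand_theta = theta + step
                candidate = unflatten(current, cand_theta)
                new_sse = sse_loss(candidate, X, Y)
                _check_finite(new_sse, epochs_done + 1)
                new_ew = 0.5 * float(cand_theta @ cand_theta)
                new_obj = beta * new_sse + alpha * new_ew
                if new_obj < objective:
                    theta, current = cand_theta, candidate
                    sse, e_w, objective = new_sse, new_ew, new_obj
                    lam = max(lam / config.lm_lambda_factor, 1e-20)
                    accepted = True
                    break
                lam *= config.lm_lambda_factor
            if not accepted:
                stop = "lambda_overflow"
                break
            epochs_done += 1
            history.append(sse)
            obj_history.append(objective)
            inner_accepted = True
            logger.info(
                "bayes_reg epoch %d sse=%.6g obj=%.6g alpha=%.3g beta=%.3g",
                epochs_done,
                sse,
                objective,
                alpha,
                beta,
            )
            break  # one accepted step per outer iteration, then re-estimate
        if stop in ("goal", "gradient"):
            break
        if not inner_accepted:
            break
        # evidence re-estimation of alpha, beta and the effective parameter count
        J = jacobian(current, X)
        H = beta * (J.T @ J) + max(alpha, 1e-12) * np.eye(n_params)
        try:
            H_inv = np.linalg.inv(H)
            gamma = n_params - max(alpha, 1e-12) * float(np.trace(H_inv))
        except np.linalg.LinAlgError:
            gamma = float(n_params)
        gamma = float(np.clip(gamma, 0.0, n_params))
        gamma_history.append(gamma)
        alpha = min(gamma / max(2.0 * e_w, 1e-12), HYPER_CAP)
        beta = min((n_resid - gamma) / max(2.0 * sse, 1e-12), HYPER_CAP)
        beta = max(beta, 1e-12)
        objective = beta * sse + alpha * e_w
    if epochs_done >= config.max_epochs:
        stop = "max_epochs" if stop not in ("goal", "gradient") else stop
    run = TrainRun(current, history, stop, epochs_done)
    run.alpha, run.beta, run.gamma = alpha, beta, gamma
    run.gamma_history = gamma_history
    run.objective_history = obj_history
    return run


# ---------------------------------------------------------------------------
# batch quasi-Newton wrappers


def _train_quasi_newton(model: MLPModel, X, Y, config: TrainConfig) -> TrainRun:
    theta0 = flatten(model)

    def f(theta: np.ndarray) -> float:
        return sse_loss(unflatten(model, theta), X, Y)

    def g(theta: np.ndarray) -> np.ndarray:
        return gradient(unflatten(model, theta), X, Y)

    minimize = bfgs_minimize if config.algorithm == "bfgs" else oss_minimize
    result = minimize(
        f,
        g,
        theta0,
        max_iter=config.max_epochs,
        gtol=config.gradient_tolerance,
        f_goal=config.goal_sse,
    )
    final = unflatten(model, result.x)
    stop = {
        "goal": "goal",
        "gtol": "gradient",
        "stalled": "gradient",
        "max_iter": "max_epochs",
    }[result.stop]
    return TrainRun(final, result.history, stop, result.n_iter)


# ---------------------------------------------------------------------------
# incremental per-sample trainers


def _train_incremental(model: MLPModel, X, Y, config: TrainConfig) -> TrainRun:
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if config.algorithm == "cyclical" and config.cycle_order is not None:
        order = list(config.cycle_order)
        if sorted(order) != list(range(n)):
            raise ValueError("cycle_order must be a permutation of the sample indices")
    else:
        order = list(range(n))
    current = model
    sse = sse_loss(current, X, Y)
    history = [sse]
    stop = "max_epochs"
    for epoch in range(1, config.max_epochs + 1):
        if sse <= config.goal_sse:
            stop = "goal"
            break
        for i in order:
            g = gradient(current, X[i : i + 1], Y[i : i + 1])
            theta = flatten(current) - config.learning_rate * g
            current = unflatten(current, theta)
        sse = sse_loss(current, X, Y)
        _check_finite(sse, epoch)
        history.append(sse)
        logger.info("%s epoch %d sse=%.6g", config.algorithm, epoch, sse)
        g_full = gradient(current, X, Y)
        if np.max(np.abs(g_full)) < config.gradient_tolerance:
            stop = "gradient"
            break
    if sse <= config.goal_sse and stop == "max_epochs":
        stop = "goal"
    return TrainRun(current, history, stop, len(history) - 1)


# ---------------------------------------------------------------------------
# dispatch


def train(model: MLPModel, X, Y, config: TrainConfig) -> TrainRun:
    """Train a network with the configured algorithm.

    Returns the final model plus the per-epoch loss history and stop reason;
    ``max_epochs=0`` returns the input model untouched.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.size == 0:
        raise ValueError("training data must be nonempty")
    if config.max_epochs == 0:
        return TrainRun(model, [sse_loss(model, X, Y)], "max_epochs", 0)
    if config.algorithm == "lm":
        return _train_lm(model, X, Y, config)
    if config.algorithm == "bayes_reg":
        return _train_bayes_reg(model, X, Y, config)
    if config.algorithm in ("oss", "bfgs"):
        return _train_quasi_newton(model, X, Y, config)
    return _train_incremental(model, X, Y, config)


def sweep_hidden_units(
    records: Sequence,
    algorithm: str,
    unit_list: Sequence[int],
    folds: int = 10,
    seed: int = 0,
    max_epochs: int = 50,
):
    """Cross-validate one algorithm across hidden-unit counts.

    Returns a DataFrame with one row per unit count and the mean success rate
    per output parameter — the hidden-unit sweep used to pick a
    configuration.
    """
    import pandas as pd

    from .evaluation import cross_validate

    if not unit_list:
        raise ValueError("unit_list must be nonempty")
    rows = []
    for units in unit_list:
        config = TrainConfig(
            algorithm=algorithm, hidden_units=int(units), max_epochs=max_epochs, seed=seed
        )
        try:
            report = cross_validate(records, config, k=folds, seed=seed)
        except Exception as exc:
            raise RuntimeError(f"cross-validation failed at hidden_units={units}") from exc
        row = {"hidden_units": int(units)}
        for output, stats in report.per_output.items():
            row[output] = stats.mean
        rows.append(row)
    return pd.DataFrame(rows)
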