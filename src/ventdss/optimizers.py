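"""Generic smooth minimizers used by the batch trainers.

Both quasi-Newton schemes operate on plain (loss, gradient) callables over a
flat parameter vector, so they can be exercised on analytic test functions
(e.g. convex quadratics) independently of any network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

ARMIJO_C = 1e-4
MAX_LINESEARCH = 30


@dataclass
class MinimizeResult:
    x: np.ndarray
    fun: float
    n_iter: int
    converged: bool
    history: list[float]
    stop: str = "max_iter"  # one of: goal, gtol, stalled, max_iter


def backtracking_line_search(
    f: Callable[[np.ndarray], float],
    x: np.ndarray,
    fx: float,
    g: np.ndarray,
    direction: np.ndarray,
    t0: float = 1.0,
) -> tuple[float, float] | None:
    """Armijo backtracking: halve the step until sufficient decrease.

    Returns (step, new loss) or None if no acceptable step was found in
    MAX_LINESEARCH halvings.
    """
    slope = float(g @ direction)
    if slope >= 0:
        return None
    t = t0
    for _ in range(MAX_LINESEARCH):
        fnew = f(x + t * direction)
        if np.isfinite(fnew) and fnew <= fx + ARMIJO_C * t * slope:
            return t, fnew
        t *= 0.5
    return None


def bfgs_minimize(
    f: Callable[[np.ndarray], float],
    grad: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    max_iter: int = 200,
    gtol: float = 1e-8,
    f_goal: float = -np.inf,
) -> MinimizeResult:
    """Dense BFGS with inverse-Hessian updates and Armijo backtracking.

    The curvature condition s'y > 0 guards every update; steps that fail it
    leave the inverse Hessian unchanged.  Stops on gradient norm, loss goal,
    iteration budget, or when no descent step exists.
    """
    x = np.asarray(x0, dtype=float).copy()
    n = x.size
    H = np.eye(n)
    first_update = True
    g = grad(x)
    fx = f(x)
    history = [fx]
    for it in range(1, max_iter + 1):
        if fx <= f_goal:
            return MinimizeResult(x, fx, it - 1, True, history, "goal")
        if np.max(np.abs(g)) < gtol:
            return MinimizeResult(x, fx, it - 1, True, history, "gtol")
        d = -H @ g
        ls = backtracking_line_search(f, x, fx, g, d)
        if ls is None:
            # reset to steepest descent once; give up if that fails too
            H = np.eye(n)
            d = -g
            ls = backtracking_line_search(f, x, fx, g, d)
            if ls is None:
                return MinimizeResult(x, fx, it - 1, False, history, "stalled")
        t, fnew = ls
        x_new = x + t * d
        g_new = grad(x_new)
        s = x_new - x
        y = g_new - g
        sy = float(s @ y)
        if sy > 1e-12:
            if first_update:
                # standard initial scaling: makes the first quasi-Newton
                # step well sized so unit steps are accepted thereafter
                H = (sy / float(y @ y)) * np.eye(n)
                first_update = False
            rho = 1.0 / sy
            V = np.eye(n) - rho * np.outer(s, y)
            H = V @ H @ V.T + rho * np.outer(s, s)
        x, g, fx = x_new, g_new, fnew
        history.append(fx)
    if fx <= f_goal:
        return MinimizeResult(x, fx, max_iter, True, history, "goal")
    converged = bool(np.max(np.abs(g)) < gtol)
    return MinimizeResult(
        x, fx, max_iter, converged, history, "gtol" if converged else "max_iter"
    )


def oss_minimize(
    f: Callable[[np.ndarray], float],
    grad: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    max_iter: int = 200,
    gtol: float = 1e-8,
    f_goal: float = -np.inf,
) -> MinimizeResult:
    """One-step secant method: a memoryless quasi-Newton direction.

    The search direction combines the current gradient with the previous step
    and gradient change (Battiti's one-step secant rule), avoiding any stored
    matrix.  Directions that fail the descent test fall back to steepest
    descent.
    """
    x = np.asarray(x0, dtype=float).copy()
    g = grad(x)
    fx = f(x)
    history = [fx]
    s_prev: np.ndarray | None = None
    y_prev: np.ndarray | None = None
    for it in range(1, max_iter + 1):
        if fx <= f_goal:
            return MinimizeResult(x, fx, it - 1, True, history, "goal")
        if np.max(np.abs(g)) < gtol:
            return MinimizeResult(x, fx, it - 1, True, history, "gtol")
        if s_prev is None or y_prev is None:
            d = -g
        else:
            sy = float(s_prev @ y_prev)
            if sy <= 1e-12:
                d = -g
            else:
                sg = float(s_prev @ g)
                yg = float(y_prev @ g)
                yy = float(y_prev @ y_prev)
                A = -(1.0 + yy / sy) * (sg / sy) + yg / sy
                B = sg / sy
                d = -g + A * s_prev + B * y_prev
        ls = backtracking_line_search(f, x, fx, g, d)
        if ls is None and not np.array_equal(d, -g):
            d = -g
            ls = backtracking_line_search(f, x, fx, g, d)
        if ls is None:
            return MinimizeResult(x, fx, it - 1, False, history, "stalled")
        t, fnew = ls
        x_new = x + t * d
        g_new = grad(x_new)
        s_prev = x_new - x
        y_prev = g_new - g
        x, g, fx = x_new, g_new, fnew
        history.append(fx)
    if fx <= f_goal:
        return MinimizeResult(x, fx, max_iter, True, history, "goal")
    converged = bool(np.max(np.abs(g)) < gtol)
    return MinimizeResult(
        x, fx, max_iter, converged, history, "gtol" if converged else "max_iter"
    )
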