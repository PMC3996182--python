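"""Success metrics, k-fold cross-validation harness and benchmark reports.

Regression "success" for a ventilator setting is the complement of the
normalized mean absolute error: 100 * (1 - mean(|yhat - y| / range)), floored
at zero, where the reference range of each output is taken from the training
folds only.  An alternative within-tolerance definition (percent of
predictions within +/- tau of the truth) is selectable.  Classification
success is plain percent agreement.  Cross-validation fits the feature
scaler and both network heads on the k-1 training folds and scores on the
held-out fold, so no test-fold information reaches training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .bayes import round_half_away
from .estimators import MLPVentilatorRegressor, SupportModeClassifier
from .records import (
    PatientRecord,
    REGRESSION_OUTPUTS,
    cohort_to_matrix,
    cohort_to_targets,
)
from .training import TrainConfig

OUTPUT_NAMES = REGRESSION_OUTPUTS + ("ps_vs",)


@dataclass(frozen=True)
class FoldPlan:
    """k disjoint index lists covering 0..n-1 with sizes differing by <= 1."""

    folds: tuple[tuple[int, ...], ...]
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)


@dataclass
class OutputStats:
    """Per-output fold success rates with their mean and sample s."""

    fold_scores: list[float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_scores))

    @property
    def std(self) -> float:
        if len(self.fold_scores) < 2:
            return 0.0
        return float(np.std(self.fold_scores, ddof=1))


@dataclass
class CVReport:
    """Cross-validation outcome for one algorithm/configuration."""

    algorithm: str
    hidden_units: int
    k: int
    seed: int
    per_output: dict[str, OutputStats] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """One row per output: fold scores, mean and s."""
        rows = []
        for name, stats in self.per_output.items():
            rows.append(
                {
                    "output": name,
                    "mean": stats.mean,
                    "s": stats.std,
                    **{f"fold_{i}": v for i, v in enumerate(stats.fold_scores)},
                }
            )
        return pd.DataFrame(rows)

    def summary_row(self) -> dict[str, str]:
        """Benchmark-table cell formatting: "mean ±s" per output."""
        row = {"algorithm": self.algorithm}
        for name in OUTPUT_NAMES:
            stats = self.per_output[name]
            row[name] = f"{stats.mean:.3f} ±{stats.std:.3f}"
        return row


def kfold_indices(n: int, k: int, seed: int) -> FoldPlan:
    """Seeded shuffle followed by a contiguous split into k balanced folds."""
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    folds = tuple(
        tuple(int(i) for i in test_idx)
        for _, test_idx in splitter.split(np.arange(n))
    )
    return FoldPlan(folds=folds, seed=seed)


def regression_success(
    predictions: np.ndarray,
    truths: np.ndarray,
    reference_range: np.ndarray | float,
    mode: str = "nmae",
    tolerance_fraction: float = 0.05,
) -> np.ndarray:
    """Percent success per output column.

    ``nmae``: 100 * (1 - mean(|err| / range)), floored at 0.
    ``tolerance``: percent of predictions within tolerance_fraction * range
    of the truth.
    """
    yhat = np.atleast_2d(np.asarray(predictions, dtype=float))
    y = np.atleast_2d(np.asarray(truths, dtype=float))
    if yhat.shape != y.shape:
        raise ValueError("prediction and truth shapes differ")
    rng = np.broadcast_to(np.asarray(reference_range, dtype=float), (y.shape[1],))
    if np.any(rng <= 0):
        raise ValueError("reference_range must be positive for every output")
    err = np.abs(yhat - y)
    if mode == "nmae":
        return np.maximum(0.0, 100.0 * (1.0 - (err / rng).mean(axis=0)))
    if mode == "tolerance":
        within = err <= tolerance_fraction * rng
        return 100.0 * within.mean(axis=0)
    raise ValueError(f"unknown success mode {mode!r}")


def classification_success(predicted: Sequence, truth: Sequence) -> float:
    """Percent of mode predictions agreeing with the truth."""
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    if pred.shape != true.shape:
        raise ValueError("prediction and truth lengths differ")
    if pred.size == 0:
        raise ValueError("cannot score an empty set")
    return 100.0 * float(np.mean(pred == true))


def cross_validate(
    records: Sequence[PatientRecord],
    config: TrainConfig,
    k: int = 10,
    seed: int = 0,
    success_mode: str = "nmae",
) -> CVReport:
    """k-fold cross-validation of both network heads on a complete cohort.

    For each fold the input scaler, the output reference ranges and both
    networks are fit on the k-1 training folds; the held-out fold only ever
    provides test inputs and truths.
    """
    records = list(records)
    X = cohort_to_matrix(records)
    Y, modes = cohort_to_targets(records)
    plan = kfold_indices(len(records), k, seed)
    if min(len(f) for f in plan.folds) < 2:
        raise ValueError("every fold must contain at least 2 records")

    scores: dict[str, list[float]] = {name: [] for name in OUTPUT_NAMES}
    all_idx = np.arange(len(records))
    for test_idx in plan.folds:
        test_idx = np.asarray(test_idx)
        train_idx = np.setdiff1d(all_idx, test_idx)
        X_tr, X_te = X[train_idx], X[test_idx]
        Y_tr, Y_te = Y[train_idx], Y[test_idx]
        m_tr, m_te = modes[train_idx], modes[test_idx]

        reg = MLPVentilatorRegressor(
            hidden_units=config.hidden_units,
            algorithm=config.algorithm,
            max_epochs=config.max_epochs,
            goal_sse=config.goal_sse,
            gradient_tolerance=config.gradient_tolerance,
            learning_rate=config.learning_rate,
            lm_lambda_init=config.lm_lambda_init,
            lm_lambda_factor=config.lm_lambda_factor,
            random_state=config.seed,
        ).fit(X_tr, Y_tr)
        clf = SupportModeClassifier(
            hidden_units=config.hidden_units,
            algorithm=config.algorithm,
            max_epochs=config.max_epochs,
            goal_sse=config.goal_sse,
            gradient_tolerance=config.gradient_tolerance,
            learning_rate=config.learning_rate,
            lm_lambda_init=config.lm_lambda_init,
            lm_lambda_factor=config.lm_lambda_factor,
            random_state=config.seed,
        ).fit(X_tr, m_tr)

        ranges = Y_tr.max(axis=0) - Y_tr.min(axis=0)
        if np.any(ranges <= 0):  # constant training output: score against unit span
            ranges = np.where(ranges <= 0, 1.0, ranges)
        reg_scores = regression_success(reg.predict(X_te), Y_te, ranges, mode=success_mode)
        for name, value in zip(REGRESSION_OUTPUTS, reg_scores):
            scores[name].append(float(value))
        scores["ps_vs"].append(classification_success(clf.predict(X_te), m_te))

    report = CVReport(
        algorithm=config.algorithm,
        hidden_units=config.hidden_units,
        k=plan.k,
        seed=seed,
    )
    report.per_output = {name: OutputStats(vals) for name, vals in scores.items()}
    return report


def overall_accuracy(best_rates: Sequence[float]) -> float:
    """Arithmetic mean of the four best per-output rates, at 2 decimals.

    This is the single headline figure aggregating the best frequency, tidal
    volume, FiO2 and mode success percentages.
    """
    rates = np.asarray(best_rates, dtype=float)
    if rates.shape != (4,):
        raise ValueError("exactly four per-output rates required")
    if np.any((rates < 0) | (rates > 100)):
        raise ValueError("rates must lie in [0, 100]")
    return round_half_away(float(rates.mean()), 2)


def benchmark(
    records: Sequence[PatientRecord],
    algorithms: Sequence[str],
    hidden_units: int = 10,
    max_epochs: int = 50,
    k: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[CVReport]]:
    """Run cross-validation for several algorithms and tabulate "mean ±s".

    Returns the benchmark-format summary table (one algorithm per row, one
    column per output) together with the full per-fold reports.
    """
    reports = []
    for algorithm in algorithms:
        config = TrainConfig(
            algorithm=algorithm,
            hidden_units=hidden_units,
            max_epochs=max_epochs,
            seed=seed,
        )
        reports.append(cross_validate(records, config, k=k, seed=seed))
    table = pd.DataFrame([r.summary_row() for r in reports])
    return table, reports
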