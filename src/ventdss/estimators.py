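"""Scikit-learn style estimators over the network engine and trainers.

:class:`MLPVentilatorRegressor` predicts the three continuous ventilator
settings (frequency in breaths/min, tidal volume in mL, FiO2 as a fraction);
:class:`SupportModeClassifier` predicts the pressure-/volume-support mode.
Both follow the sklearn contract (``get_params``/``set_params``, fitted
attributes with trailing underscores, ``fit``/``predict``), so they compose
with pipelines and model selection; :class:`FindingFrequencyModel` is the
stage-1 disease scorer fit from a labeled cohort.

Inputs X are the raw 10-column feature matrices of
:func:`ventdss.records.cohort_to_matrix`; scaling to [-1, 1] is fit inside
``fit`` (training data only) when enabled.  The regressor also scales its
targets internally so that the incremental trainers remain stable at raw
clinical magnitudes; predictions are returned on the original scale.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from . import bayes
from .network import forward, init_mlp
from .records import FeatureScaler, PatientRecord
from .training import TrainConfig, TrainRun, train


def _make_config(est, algorithm: str) -> TrainConfig:
    return TrainConfig(
        algorithm=algorithm,
        hidden_units=est.hidden_units,
        max_epochs=est.max_epochs,
        goal_sse=est.goal_sse,
        gradient_tolerance=est.gradient_tolerance,
        learning_rate=est.learning_rate,
        lm_lambda_init=est.lm_lambda_init,
        lm_lambda_factor=est.lm_lambda_factor,
        seed=est.random_state,
    )


class MLPVentilatorRegressor(BaseEstimator, RegressorMixin):
    """Single-hidden-layer tanh network regressing the continuous settings.

    Parameters mirror :class:`ventdss.training.TrainConfig`; ``algorithm`` is
    one of lm, bayes_reg, oss, bfgs, cyclical, sequential.
    """

    def __init__(
        self,
        hidden_units: int = 30,
        algorithm: str = "lm",
        max_epochs: int = 200,
        goal_sse: float = 0.0,
        gradient_tolerance: float = 1e-10,
        learning_rate: float = 0.01,
        lm_lambda_init: float = 1e-3,
        lm_lambda_factor: float = 10.0,
        scale_inputs: bool = True,
        random_state: int = 0,
    ):
        self.hidden_units = hidden_units
        self.algorithm = algorithm
        self.max_epochs = max_epochs
        self.goal_sse = goal_sse
        self.gradient_tolerance = gradient_tolerance
        self.learning_rate = learning_rate
        self.lm_lambda_init = lm_lambda_init
        self.lm_lambda_factor = lm_lambda_factor
        self.scale_inputs = scale_inputs
        self.random_state = random_state

    def fit(self, X, y) -> "MLPVentilatorRegressor":
        X, y = check_X_y(X, y, multi_output=True, y_numeric=True)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        self.n_features_in_ = X.shape[1]
        self.n_outputs_ = y.shape[1]
        self.input_scaler_ = FeatureScaler(enabled=self.scale_inputs).fit(X)
        self.target_scaler_ = FeatureScaler(enabled=True).fit(y)
        Xs = self.input_scaler_.transform(X)
        ys = self.target_scaler_.transform(y)
        model = init_mlp(
            (X.shape[1], self.hidden_units, y.shape[1]),
            seed=self.random_state,
            output_activation="identity",
        )
        config = _make_config(self, self.algorithm)
        self.train_run_: TrainRun = train(model, Xs, ys, config)
        self.model_ = self.train_run_.model
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = check_array(X)
        Xs = self.input_scaler_.transform(X)
        out = forward(self.model_, Xs)
        return self.target_scaler_.inverse_transform(out)


class SupportModeClassifier(BaseEstimator, ClassifierMixin):
    """Logistic-output network classifying pressure vs volume support.

    Trained on 0/1 labels (1 = pressure support) with squared error on the
    logistic output; the decision threshold is 0.5, with an exact 0.5 scored
    as pressure support (the majority mode in all three disease cohorts).
    """

    def __init__(
        self,
        hidden_units: int = 5,
        algorithm: str = "bayes_reg",
        max_epochs: int = 200,
        goal_sse: float = 0.0,
        gradient_tolerance: float = 1e-10,
        learning_rate: float = 0.01,
        lm_lambda_init: float = 1e-3,
        lm_lambda_factor: float = 10.0,
        scale_inputs: bool = True,
        random_state: int = 0,
    ):
        self.hidden_units = hidden_units
        self.algorithm = algorithm
        self.max_epochs = max_epochs
        self.goal_sse = goal_sse
        self.gradient_tolerance = gradient_tolerance
        self.learning_rate = learning_rate
        self.lm_lambda_init = lm_lambda_init
        self.lm_lambda_factor = lm_lambda_factor
        self.scale_inputs = scale_inputs
        self.random_state = random_state

    def fit(self, X, y) -> "SupportModeClassifier":
        X, y = check_X_y(X, y)
        y = np.asarray(y, dtype=float)
        labels = np.unique(y)
        if not np.all(np.isin(labels, (0.0, 1.0))):
            raise ValueError("labels must be binary 0/1 (1 = pressure support)")
        self.classes_ = np.array([0.0, 1.0])
        self.n_features_in_ = X.shape[1]
        self.input_scaler_ = FeatureScaler(enabled=self.scale_inputs).fit(X)
        Xs = self.input_scaler_.transform(X)
        model = init_mlp(
            (X.shape[1], self.hidden_units, 1),
            seed=self.random_state,
            output_activation="logistic",
        )
        config = _make_config(self, self.algorithm)
        self.train_run_: TrainRun = train(model, Xs, y[:, None], config)
        self.model_ = self.train_run_.model
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = check_array(X)
        p1 = forward(self.model_, self.input_scaler_.transform(X))[:, 0]
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        p1 = self.predict_proba(X)[:, 1]
        return (p1 >= 0.5).astype(float)


class FindingFrequencyModel(BaseEstimator, ClassifierMixin):
    """Stage-1 disease scorer fit from a labeled patient cohort.

    ``fit`` binarizes each patient's findings and tallies per-disease
    occurrence counts; ``predict`` ranks the three diseases by the
    self-weighted average of the occurrence proportions of the findings the
    patient presents.  Can also be constructed directly from reference
    finding tables via :meth:`from_tables`.
    """

    def __init__(self, thresholds=None):
        self.thresholds = thresholds

    def fit(self, records: Sequence[PatientRecord], y=None) -> "FindingFrequencyModel":
        from .synthetic import cohort_to_finding_tables

        self.tables_ = cohort_to_finding_tables(records, self.thresholds)
        return self

    @classmethod
    def from_tables(cls, tables, thresholds=None) -> "FindingFrequencyModel":
        est = cls(thresholds=thresholds)
        est.tables_ = list(tables)
        return est

    def score_record(self, record: PatientRecord) -> list[bayes.DiseaseScore]:
        check_is_fitted(self, "tables_")
        presence = bayes.binarize_findings(record, self.thresholds, missing="absent")
        return bayes.rank_diseases(presence, self.tables_)

    def predict(self, records: Sequence[PatientRecord]) -> np.ndarray:
        return np.array([self.score_record(r)[0].disease for r in records])
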