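"""End-to-end recommendation pipeline: validate -> diagnose -> recommend.

A :class:`ModelBundle` packages everything stage 2 needs — the trained
regression and mode-classification networks with their input/target scalers —
together with the stage-1 finding tables, and serializes to a single JSON
document for bit-exact reload.

:func:`recommend` mirrors the physician-in-the-loop flow: a record failing
the plausibility check is blocked (its alerts are returned instead of
settings) unless an explicit override is given, and the stage-1 disease
ranking is reported alongside the recommended settings so the physician can
confirm or replace the diagnosis before acting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from . import network
from .bayes import DiseaseScore, FindingTable, tables_from_json, tables_to_json
from .estimators import (
    FindingFrequencyModel,
    MLPVentilatorRegressor,
    SupportModeClassifier,
)
from .records import (
    FeatureScaler,
    PatientRecord,
    ValidationReport,
    record_to_input_row,
    validate_record,
)


@dataclass
class ModelBundle:
    """Trained stage-2 networks plus stage-1 finding tables."""

    regressor: MLPVentilatorRegressor
    classifier: SupportModeClassifier
    tables: list[FindingTable]

    def to_json(self) -> str:
        payload = {
            "regressor": {
                "model": json.loads(network.to_json(self.regressor.model_)),
                "input_scaler": self.regressor.input_scaler_.to_dict(),
                "target_scaler": self.regressor.target_scaler_.to_dict(),
                "params": self.regressor.get_params(),
            },
            "classifier": {
                "model": json.loads(network.to_json(self.classifier.model_)),
                "input_scaler": self.classifier.input_scaler_.to_dict(),
                "params": self.classifier.get_params(),
            },
            "tables": json.loads(tables_to_json(self.tables)),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ModelBundle":
        payload = json.loads(text)
        reg = MLPVentilatorRegressor(**payload["regressor"]["params"])
        reg.model_ = network.from_json(json.dumps(payload["regressor"]["model"]))
        reg.input_scaler_ = FeatureScaler.from_dict(payload["regressor"]["input_scaler"])
        reg.target_scaler_ = FeatureScaler.from_dict(
            payload["regressor"]["target_scaler"]
        )
        reg.n_features_in_ = reg.model_.n_inputs
        clf = SupportModeClassifier(**payload["classifier"]["params"])
        clf.model_ = network.from_json(json.dumps(payload["classifier"]["model"]))
        clf.input_scaler_ = FeatureScaler.from_dict(
            payload["classifier"]["input_scaler"]
        )
        clf.classes_ = np.array([0.0, 1.0])
        clf.n_features_in_ = clf.model_.n_inputs
        tables = tables_from_json(json.dumps(payload["tables"]))
        return cls(regressor=reg, classifier=clf, tables=tables)


@dataclass
class Recommendation:
    """Outcome of one recommendation request."""

    patient_id: str
    validation: ValidationReport
    blocked: bool
    disease_scores: list[DiseaseScore] | None = None
    accepted_disease: str | None = None
    frequency: float | None = None
    tidal_volume: float | None = None
    fio2: float | None = None
    support_mode: str | None = None

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "blocked": self.blocked,
            "alerts": [
                {"field": a.field, "value": a.value, "low": a.low, "high": a.high}
                for a in self.validation.alerts
            ],
            "disease_scores": (
                [
                    {"disease": s.disease, "score": s.score}
                    for s in self.disease_scores
                ]
                if self.disease_scores
                else None
            ),
            "accepted_disease": self.accepted_disease,
            "settings": (
                None
                if self.blocked
                else {
                    "frequency": self.frequency,
                    "tidal_volume": self.tidal_volume,
                    "fio2": self.fio2,
                    "support_mode": self.support_mode,
                }
            ),
        }


def recommend(
    record: PatientRecord,
    bundle: ModelBundle,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    accept_diagnosis: bool = True,
    override_validation: bool = False,
) -> Recommendation:
    """Run the full two-stage pipeline on one patient record.

    Stage 1 validates the entries and ranks the candidate diseases; stage 2
    only runs once the record is plausible (or explicitly overridden) and a
    disease is accepted — either the record's own label or, with
    ``accept_diagnosis``, the top-ranked disease.
    """
    report = validate_record(record, ranges)
    if not report.ok and not override_validation:
        return Recommendation(record.patient_id, report, blocked=True)

    stage1 = FindingFrequencyModel.from_tables(bundle.tables)
    try:
        scores = stage1.score_record(record)
    except ValueError:
        # no findings present: automatic ranking is undefined
        scores = None
    disease = record.disease
    if disease is None:
        if scores is None or not accept_diagnosis:
            return Recommendation(
                record.patient_id, report, blocked=True, disease_scores=scores
            )
        disease = scores[0].disease

    working = replace(record, disease=disease)
    x = record_to_input_row(working)[None, :]
    settings = bundle.regressor.predict(x)[0]
    mode = "PS" if bundle.classifier.predict(x)[0] >= 0.5 else "VS"
    return Recommendation(
        patient_id=record.patient_id,
        validation=report,
        blocked=False,
        disease_scores=scores,
        accepted_disease=disease,
        frequency=float(settings[0]),
        tidal_volume=float(settings[1]),
        fio2=float(np.clip(settings[2], 0.21, 1.0)),
        support_mode=mode,
    )


def fit_bundle(
    records: Sequence[PatientRecord],
    regressor: MLPVentilatorRegressor | None = None,
    classifier: SupportModeClassifier | None = None,
) -> ModelBundle:
    """Fit both stage-2 heads and tally stage-1 tables from a labeled cohort."""
    from .records import cohort_to_matrix, cohort_to_targets
    from .synthetic import cohort_to_finding_tables

    X = cohort_to_matrix(records)
    Y, modes = cohort_to_targets(records)
    reg = regressor if regressor is not None else MLPVentilatorRegressor()
    clf = classifier if classifier is not None else SupportModeClassifier()
    reg.fit(X, Y)
    clf.fit(X, modes)
    tables = cohort_to_finding_tables(records)
    return ModelBundle(regressor=reg, classifier=clf, tables=tables)
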