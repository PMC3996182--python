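"""Patient records, cohort CSV I/O, plausibility validation and feature encoding.

A :class:`PatientRecord` holds the 15 physiological/ventilation fields of one
ICU patient (daily-averaged values): ten model inputs (diagnosed disease, core
body temperature, pulse, arterial systolic pressure, diastolic blood pressure,
PEEP, pSO2, pH, pCO2, bicarbonate) plus pO2, and four ventilator-setting
outputs (frequency, tidal volume, FiO2, pressure/volume support mode).  The
outputs are optional: a record awaiting a recommendation carries only inputs.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.preprocessing import MinMaxScaler

DISEASES = ("COPD", "ARDS", "CVD")

#: Numeric code used when the disease enters the network as a feature.
DISEASE_CODES = {"COPD": 1.0, "ARDS": 2.0, "CVD": 3.0}

#: The ten network inputs, in their fixed feature order.
INPUT_FIELDS = (
    "disease",
    "core_body_temperature",
    "pulse",
    "arterial_systolic_pressure",
    "diastolic_blood_pressure",
    "peep",
    "pso2",
    "ph",
    "pco2",
    "bicarbonate",
)

#: The three continuous setting outputs (regression head), fixed order.
REGRESSION_OUTPUTS = ("frequency", "tidal_volume", "fio2")

SUPPORT_MODES = ("PS", "VS")

#: All numeric measurement fields a record may carry.
NUMERIC_FIELDS = (
    "core_body_temperature",
    "pulse",
    "arterial_systolic_pressure",
    "diastolic_blood_pressure",
    "peep",
    "pso2",
    "ph",
    "po2",
    "pco2",
    "bicarbonate",
    "frequency",
    "tidal_volume",
    "fio2",
)

CSV_COLUMNS = (
    "patient_id",
    "disease",
    "core_body_temperature",
    "pulse",
    "arterial_systolic_pressure",
    "diastolic_blood_pressure",
    "peep",
    "pso2",
    "ph",
    "po2",
    "pco2",
    "bicarbonate",
    "frequency",
    "tidal_volume",
    "fio2",
    "support_mode",
)

#: Default plausibility windows (artifact defaults, configurable per site).
DEFAULT_PLAUSIBILITY_RANGES: dict[str, tuple[float, float]] = {
    "core_body_temperature": (30.0, 43.0),
    "pulse": (20.0, 220.0),
    "arterial_systolic_pressure": (50.0, 260.0),
    "diastolic_blood_pressure": (20.0, 160.0),
    "peep": (0.0, 25.0),
    "pso2": (40.0, 100.0),
    "ph": (6.8, 7.8),
    "po2": (20.0, 600.0),
    "pco2": (10.0, 130.0),
    "bicarbonate": (5.0, 45.0),
    "frequency": (4.0, 60.0),
    "tidal_volume": (100.0, 1200.0),
    "fio2": (0.21, 1.0),
}


class CohortFormatError(ValueError):
    """Raised when a cohort stream does not match the expected CSV layout."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient's daily-averaged physiology and (optionally) settings.

    FiO2 is stored as a fraction in [0.21, 1.0]; ``support_mode`` is ``"PS"``
    (pressure support) or ``"VS"`` (volume support).
    """

    patient_id: str
    disease: str | None = None
    core_body_temperature: float | None = None
    pulse: float | None = None
    arterial_systolic_pressure: float | None = None
    diastolic_blood_pressure: float | None = None
    peep: float | None = None
    pso2: float | None = None
    ph: float | None = None
    po2: float | None = None
    pco2: float | None = None
    bicarbonate: float | None = None
    frequency: float | None = None
    tidal_volume: float | None = None
    fio2: float | None = None
    support_mode: str | None = None

    def __post_init__(self) -> None:
        if self.disease is not None and self.disease not in DISEASES:
            raise ValueError(f"unknown disease label {self.disease!r}")
        if self.support_mode is not None and self.support_mode not in SUPPORT_MODES:
            raise ValueError(f"unknown support mode {self.support_mode!r}")
        # implausible values (e.g. a pH of 9.0) are deliberately constructible:
        # they are exactly what the faulty-entry validation must catch
        for name in NUMERIC_FIELDS:
            value = getattr(self, name)
            if value is not None and not math.isfinite(value):
                raise ValueError(f"non-finite value for {name}: {value!r}")

    def has_inputs(self) -> bool:
        """True when all ten network-input fields are present."""
        return all(getattr(self, f) is not None for f in INPUT_FIELDS)

    def has_outputs(self) -> bool:
        """True when all four ventilator-setting outputs are present."""
        return (
            all(getattr(self, f) is not None for f in REGRESSION_OUTPUTS)
            and self.support_mode is not None
        )


@dataclass(frozen=True)
class Alert:
    """A single plausibility violation: which field, what value, which bound."""

    field: str
    value: float
    low: float
    high: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}={self.value:g} outside [{self.low:g}, {self.high:g}]"


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of the possible-faulty-entry check for one record."""

    patient_id: str
    alerts: tuple[Alert, ...]

    @property
    def ok(self) -> bool:
        return not self.alerts


def normalize_fio2(value: float) -> float:
    """Accept both fraction ([0.21, 1]) and percent (>1) FiO2 dialects.

    Clinical sources mix "45%" and "0.45"; anything above 1 is read as a
    percentage and divided by 100. The stored representation is always the
    fraction.
    """
    return value / 100.0 if value > 1.0 else value


def _parse_float(raw: str, column: str, row: int) -> float:
    try:
        return float(raw)
    except ValueError as exc:
        raise CohortFormatError(
            f"non-numeric value {raw!r} in column {column!r} at data row {row}"
        ) from exc


def read_cohort(source: str | io.TextIOBase, format: str = "csv") -> list[PatientRecord]:
    """Parse a cohort CSV stream into records, preserving row order.

    Empty cells become absent fields; the FiO2 percent dialect is converted
    to a fraction on ingestion.
    """
    if format != "csv":
        raise ValueError(f"unsupported format {format!r}")
    if isinstance(source, str):
        source = io.StringIO(source)
    frame = pd.read_csv(source, dtype=str, keep_default_na=False)
    unknown = set(frame.columns) - set(CSV_COLUMNS)
    if unknown:
        raise CohortFormatError(f"unknown column(s): {sorted(unknown)}")
    missing = set(CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise CohortFormatError(f"missing column(s): {sorted(missing)}")

    records: list[PatientRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        row_map = dict(zip(frame.columns, row))
        kwargs: dict[str, object] = {"patient_id": row_map["patient_id"]}
        disease = row_map["disease"].strip()
        kwargs["disease"] = disease or None
        mode = row_map["support_mode"].strip()
        kwargs["support_mode"] = mode or None
        for name in NUMERIC_FIELDS:
            raw = row_map[name].strip()
            if not raw:
                kwargs[name] = None
                continue
            value = _parse_float(raw, name, i)
            if name == "fio2":
                value = normalize_fio2(value)
            kwargs[name] = value
        records.append(PatientRecord(**kwargs))
    return records


def write_cohort(records: Sequence[PatientRecord], format: str = "csv") -> str:
    """Serialize records to CSV so that ``read_cohort`` round-trips them.

    Numeric fields are written with 6 significant digits; FiO2 is written as
    a fraction.
    """
    if format != "csv":
        raise ValueError(f"unsupported format {format!r}")
    lines = [",".join(CSV_COLUMNS)]
    for rec in records:
        cells: list[str] = []
        for col in CSV_COLUMNS:
            value = getattr(rec, col)
            if value is None:
                cells.append("")
            elif col in ("patient_id", "disease", "support_mode"):
                cells.append(str(value))
            else:
                cells.append(f"{value:.6g}")
        lines.append(",".join(cells))
    return "\n".join(lines) + "\n"


def validate_record(
    record: PatientRecord,
    ranges: Mapping[str, tuple[float, float]] | None = None,
) -> ValidationReport:
    """Flag every numeric field strictly outside its plausibility window.

    This is the stage-1 "possible faulty entry" gate: a suspect record is
    reported to the physician rather than silently forwarded to the setting
    recommender. Fields absent from the record are not alerted (absence is a
    structural matter handled by the encoders).
    """
    if ranges is None:
        ranges = DEFAULT_PLAUSIBILITY_RANGES
    for low, high in ranges.values():
        if not low < high:
            raise ValueError("every plausibility range must satisfy low < high")
    alerts = []
    for name in NUMERIC_FIELDS:
        value = getattr(record, name)
        if value is None or name not in ranges:
            continue
        low, high = ranges[name]
        if value < low or value > high:
            alerts.append(Alert(name, value, low, high))
    return ValidationReport(record.patient_id, tuple(alerts))


def record_to_input_row(record: PatientRecord) -> np.ndarray:
    """Raw (unscaled) 10-vector in the fixed feature order.

    The disease label occupies slot 0 as its numeric code (COPD=1, ARDS=2,
    CVD=3), keeping the network input at exactly ten terms.
    """
    missing = [f for f in INPUT_FIELDS if getattr(record, f) is None]
    if missing:
        raise ValueError(f"record {record.patient_id!r} missing input field(s): {missing}")
    values = [DISEASE_CODES[record.disease]]
    values += [float(getattr(record, f)) for f in INPUT_FIELDS[1:]]
    return np.asarray(values, dtype=float)


def cohort_to_matrix(records: Iterable[PatientRecord]) -> np.ndarray:
    """Stack raw input rows for a cohort; shape (n, 10)."""
    rows = [record_to_input_row(r) for r in records]
    if not rows:
        return np.empty((0, len(INPUT_FIELDS)))
    return np.vstack(rows)


def cohort_to_targets(records: Sequence[PatientRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Regression targets (n, 3) in (frequency, tidal_volume, fio2) order and
    binary mode labels (1 = pressure support)."""
    for rec in records:
        if not rec.has_outputs():
            raise ValueError(f"record {rec.patient_id!r} lacks complete outputs")
    y = np.array(
        [[rec.frequency, rec.tidal_volume, rec.fio2] for rec in records], dtype=float
    )
    modes = np.array([1.0 if rec.support_mode == "PS" else 0.0 for rec in records])
    return y, modes


class FeatureScaler:
    """Per-feature affine map onto [-1, 1], fit on training rows only.

    Thin wrapper over :class:`sklearn.preprocessing.MinMaxScaler` that also
    supports the identity (scaling disabled). Constant features map to 0.
    """

    def __init__(self, enabled: bool = True):
        self.enabled = enabled
        self._scaler: MinMaxScaler | None = None
        self._constant: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        if self.enabled:
            self._scaler = MinMaxScaler(feature_range=(-1.0, 1.0), clip=False)
            self._scaler.fit(X)
            self._constant = X.max(axis=0) == X.min(axis=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if not self.enabled:
            return X.copy()
        if self._scaler is None:
            raise RuntimeError("scaler used before fit")
        out = self._scaler.transform(X)
        out[:, self._constant] = 0.0
        return out

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        if not self.enabled:
            return np.asarray(X, dtype=float).copy()
        if self._scaler is None:
            raise RuntimeError("scaler used before fit")
        return self._scaler.inverse_transform(np.asarray(X, dtype=float))

    def to_dict(self) -> dict:
        if not self.enabled:
            return {"enabled": False}
        if self._scaler is None:
            raise RuntimeError("scaler serialized before fit")
        return {
            "enabled": True,
            "data_min": self._scaler.data_min_.tolist(),
            "data_max": self._scaler.data_max_.tolist(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "FeatureScaler":
        scaler = cls(enabled=payload["enabled"])
        if scaler.enabled:
            lo = np.asarray(payload["data_min"], dtype=float)
            hi = np.asarray(payload["data_max"], dtype=float)
            scaler.fit(np.vstack([lo, hi]))
        return scaler


def encode_features(
    record: PatientRecord, scaler: FeatureScaler | None = None
) -> np.ndarray:
    """Encode one record as the scaled 10-vector fed to the network."""
    row = record_to_input_row(record)[None, :]
    if scaler is None:
        return row[0]
    return scaler.transform(row)[0]


def with_outputs(
    record: PatientRecord,
    frequency: float,
    tidal_volume: float,
    fio2: float,
    support_mode: str,
) -> PatientRecord:
    """Copy of a record with the four setting outputs filled in."""
    return replace(
        record,
        frequency=frequency,
        tidal_volume=tidal_volume,
        fio2=fio2,
        support_mode=support_mode,
    )
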