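"""Stage-1 diagnosis: the finding-frequency disease scoring model.

Each candidate disease (COPD, ARDS, CVD) is described by how often each of 15
clinical findings occurred in its historical cohort.  A disease's score is a
self-weighted average of those occurrence proportions: with x_n the number of
patients showing finding n out of a cohort of size N,

    p_n = x_n / N,        w_n = x_n / sum_i(x_i),        F = sum_n w_n * p_n,

which simplifies to F = sum(p^2) / sum(p).  Because the weights are the
proportions renormalized, F always lies between the smallest and largest
scored proportion and is invariant to rescaling counts into proportions.

For a specific patient the score is restricted to the findings actually
present, with the weights renormalized over that subset; scoring a patient who
presents every finding therefore recovers the full-column reference scores.

The module also ships a reference finding-frequency table for the three
diseases, with the integer counts reconstructed from 3-decimal occurrence
proportions over cohorts of 30, 65 and 63 patients (158 in total), and the
inverse-rounding routine (:func:`rationalize_column`) used to recover them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .records import DISEASES, PatientRecord

#: Fixed row order of the finding table (13 physiological + 2 mode rows).
FINDING_NAMES = (
    "core_body_temperature",
    "pulse",
    "arterial_systolic_pressure",
    "diastolic_blood_pressure",
    "fio2",
    "frequency",
    "tidal_volume",
    "peep",
    "pso2",
    "ph",
    "po2",
    "pco2",
    "bicarbonate",
    "pressure_support",
    "volume_support",
)


def round_half_away(value: float, decimals: int) -> float:
    """Round half away from zero (0.2665 -> 0.267 at 3 dp).

    Printed clinical tables follow this convention rather than banker's
    rounding, so it is applied wherever a computed proportion is compared
    against a printed cell.
    """
    scale = 10.0**decimals
    return math.copysign(math.floor(abs(value) * scale + 0.5) / scale, value)


@dataclass(frozen=True)
class FindingTable:
    """Per-disease finding occurrence counts over a historical cohort."""

    disease: str
    cohort_size: int
    counts: tuple[int, ...]
    finding_names: tuple[str, ...] = FINDING_NAMES

    def __post_init__(self) -> None:
        if self.cohort_size <= 0:
            raise ValueError("cohort_size must be positive")
        if len(self.counts) != len(self.finding_names):
            raise ValueError("one count per finding required")
        if any(c < 0 or c > self.cohort_size for c in self.counts):
            raise ValueError("counts must lie in [0, cohort_size]")
        ps = self.counts[self.finding_names.index("pressure_support")]
        vs = self.counts[self.finding_names.index("volume_support")]
        if ps + vs != self.cohort_size:
            raise ValueError(
                "pressure-support and volume-support counts must partition the cohort"
            )

    @property
    def probabilities(self) -> np.ndarray:
        """Exact occurrence proportions count/cohort_size."""
        return np.asarray(self.counts, dtype=float) / self.cohort_size

    def printed_probabilities(self, decimals: int = 3) -> np.ndarray:
        """Proportions rounded half-away-from-zero, as a printed table shows them."""
        return np.array([round_half_away(p, decimals) for p in self.probabilities])

    @property
    def pressure_support_probability(self) -> float:
        return self.probabilities[self.finding_names.index("pressure_support")]


@dataclass(frozen=True)
class DiseaseScore:
    """Score of one disease for one patient (or one full column)."""

    disease: str
    score: float
    weights: tuple[float, ...]


@dataclass(frozen=True)
class FindingPresence:
    """Binary presence of each of the 15 findings for one patient."""

    flags: tuple[bool, ...]
    finding_names: tuple[str, ...] = FINDING_NAMES

    def __post_init__(self) -> None:
        if len(self.flags) != len(self.finding_names):
            raise ValueError("one flag per finding required")

    def present_indices(self) -> list[int]:
        return [i for i, f in enumerate(self.flags) if f]


# ---------------------------------------------------------------------------
# elementary probability operations


def finding_probability(count: int, cohort_size: int) -> float:
    """Occurrence proportion of a finding: count / cohort_size."""
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    if not 0 <= count <= cohort_size:
        raise ValueError("count must lie in [0, cohort_size]")
    return count / cohort_size


def feature_weights(values: Sequence[float]) -> np.ndarray:
    """Self-normalized weights w_i = x_i / sum(x); scale-invariant, sums to 1."""
    x = np.asarray(values, dtype=float)
    if np.any(x < 0):
        raise ValueError("weights require nonnegative inputs")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero input has no defined weights")
    return x / total


def disease_probability(probabilities: Sequence[float]) -> float:
    """Self-weighted mean of occurrence proportions: F = sum(p^2)/sum(p)."""
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    w = feature_weights(p)
    return float(w @ p)


def total_probability(
    marginals: Sequence[float], conditionals: Sequence[float]
) -> float:
    """Law of total probability: P(D) = sum_i P(x_i) P(D|x_i)."""
    m = np.asarray(marginals, dtype=float)
    c = np.asarray(conditionals, dtype=float)
    if m.shape != c.shape:
        raise ValueError("marginals and conditionals must have equal length")
    if np.any((m < 0) | (m > 1)) or np.any((c < 0) | (c > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(m @ c)


def conditional_probability(joint: float, marginal: float) -> float:
    """Bayes' conditional P(D|x) = P(D and x) / P(x)."""
    if marginal <= 0:
        raise ValueError("marginal probability must be positive")
    if not 0 <= joint <= marginal <= 1:
        raise ValueError("need 0 <= joint <= marginal <= 1")
    return joint / marginal


# ---------------------------------------------------------------------------
# inverse table rounding


def rationalize_column(
    probabilities: Sequence[float], n_max: int = 200, decimals: int = 3
) -> tuple[int, list[int]]:
    """Recover (cohort_size, counts) from proportions printed at 3 decimals.

    Finds the smallest denominator n <= n_max such that every printed
    proportion p admits an integer count k with round(k/n) = p at the printed
    precision (half-away rounding).  Brute force over n; candidate counts are
    confined to round(p*n) +/- 1.
    """
    if n_max < 1:
        raise ValueError("n_max must be at least 1")
    probs = [float(p) for p in probabilities]
    for n in range(1, n_max + 1):
        counts: list[int] = []
        for p in probs:
            k0 = round(p * n)
            for k in (k0 - 1, k0, k0 + 1):
                if 0 <= k <= n and round_half_away(k / n, decimals) == round_half_away(
                    p, decimals
                ):
                    counts.append(k)
                    break
            else:
                break
        if len(counts) == len(probs):
            return n, counts
    raise ValueError(
        f"no denominator <= {n_max} reproduces all proportions at {decimals} decimals"
    )


# ---------------------------------------------------------------------------
# patient binarization and ranking

#: Default abnormality rules (config-overridable clinical conventions).
#: Each rule is (kind, params): "gt"/"lt" one-sided, "outside" two-sided.
DEFAULT_BINARIZATION: dict[str, tuple[str, tuple[float, ...]]] = {
    "core_body_temperature": ("gt", (37.5,)),
    "pulse": ("gt", (100.0,)),
    "arterial_systolic_pressure": ("outside", (90.0, 140.0)),
    "diastolic_blood_pressure": ("gt", (90.0,)),
    "fio2": ("gt", (0.25,)),  # supplemental oxygen above near-room-air
    "frequency": ("gt", (20.0,)),
    "tidal_volume": ("lt", (400.0,)),
    "peep": ("gt", (5.0,)),
    "pso2": ("lt", (90.0,)),
    "ph": ("outside", (7.35, 7.45)),
    "po2": ("lt", (80.0,)),
    "pco2": ("gt", (45.0,)),
    "bicarbonate": ("outside", (22.0, 26.0)),
}


def _apply_rule(value: float, rule: tuple[str, tuple[float, ...]]) -> bool:
    kind, params = rule
    if kind == "gt":
        return value > params[0]
    if kind == "lt":
        return value < params[0]
    if kind == "outside":
        low, high = params
        return value < low or value > high
    raise ValueError(f"unknown rule kind {kind!r}")


def binarize_findings(
    record: PatientRecord,
    thresholds: Mapping[str, tuple[str, tuple[float, ...]]] | None = None,
    missing: str = "error",
) -> FindingPresence:
    """Convert a record into the 15 binary findings of the frequency table.

    The 13 physiological findings follow the threshold rules; the two mode
    findings mirror ``support_mode`` (exactly one true when the mode is known,
    both false otherwise).  ``missing="absent"`` treats unknown fields as
    findings not present — the behaviour diagnosis needs for a patient whose
    ventilator settings have not been chosen yet.
    """
    if thresholds is None:
        thresholds = DEFAULT_BINARIZATION
    if missing not in ("error", "absent"):
        raise ValueError(f"unknown missing-field policy {missing!r}")
    flags: list[bool] = []
    for name in FINDING_NAMES:
        if name == "pressure_support":
            flags.append(record.support_mode == "PS")
            continue
        if name == "volume_support":
            flags.append(record.support_mode == "VS")
            continue
        value = getattr(record, name)
        if value is None:
            if missing == "error":
                raise ValueError(
                    f"record {record.patient_id!r} missing field {name!r} "
                    "needed for binarization"
                )
            flags.append(False)
            continue
        flags.append(_apply_rule(float(value), thresholds[name]))
    return FindingPresence(tuple(flags))


def rank_diseases(
    presence: FindingPresence, tables: Sequence[FindingTable]
) -> list[DiseaseScore]:
    """Score every disease on the findings present and sort descending.

    The score restricts the self-weighted average to the present findings
    (weights renormalized over that subset).  Ties break by the fixed disease
    order COPD < ARDS < CVD.
    """
    by_disease = {t.disease: t for t in tables}
    missing = set(DISEASES) - set(by_disease)
    if missing:
        raise ValueError(f"missing finding table(s) for {sorted(missing)}")
    idx = presence.present_indices()
    if not idx:
        raise ValueError(
            "no findings present: automatic scoring is undefined, refer to manual diagnosis"
        )
    scores: list[DiseaseScore] = []
    for disease in DISEASES:
        table = by_disease[disease]
        p = table.probabilities[idx]
        full_weights = np.zeros(len(FINDING_NAMES))
        if p.sum() == 0:
            score = 0.0
        else:
            w = feature_weights(p)
            full_weights[idx] = w
            score = float(w @ p)
        scores.append(DiseaseScore(disease, score, tuple(full_weights)))
    order = {d: i for i, d in enumerate(DISEASES)}
    return sorted(scores, key=lambda s: (-s.score, order[s.disease]))


# ---------------------------------------------------------------------------
# reference table fixture


def load_reference_tables() -> list[FindingTable]:
    """The packaged three-disease finding-frequency table (counts over 30/65/63)."""
    payload = json.loads(
        resources.files("ventdss.data").joinpath("reference_finding_counts.json").read_text()
    )
    names = tuple(payload["finding_names"])
    return [
        FindingTable(
            disease=entry["disease"],
            cohort_size=entry["cohort_size"],
            counts=tuple(entry["counts"]),
            finding_names=names,
        )
        for entry in payload["tables"]
    ]


def tables_to_json(tables: Sequence[FindingTable]) -> str:
    """Serialize finding tables to the on-disk JSON layout."""
    payload = {
        "finding_names": list(tables[0].finding_names),
        "tables": [
            {
                "disease": t.disease,
                "cohort_size": t.cohort_size,
                "counts": list(t.counts),
            }
            for t in tables
        ],
    }
    return json.dumps(payload, indent=2)


def tables_from_json(text: str) -> list[FindingTable]:
    payload = json.loads(text)
    names = tuple(payload["finding_names"])
    return [
        FindingTable(
            disease=e["disease"],
            cohort_size=e["cohort_size"],
            counts=tuple(e["counts"]),
            finding_names=names,
        )
        for e in payload["tables"]
    ]
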