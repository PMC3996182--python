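"""Synthetic patient cohorts with prescribed finding-frequency structure.

The generator emulates the statistical skeleton of a three-disease ICU
cohort: per-disease group sizes (default 30 COPD / 65 ARDS / 63 CVD, 158 in
total), per-finding abnormality frequencies matching the packaged reference
table, and ventilator-setting targets produced by a known physiological rule
so the learning stage has a recoverable signal.

Continuous values are drawn from truncated normal slices on either side of
each binarization threshold: a patient selected as "abnormal" for a finding
receives a value beyond the threshold, everyone else a value inside the
normal band, so the binarized frequencies are exact (``exact_counts`` mode)
or converge to the table cells (``bernoulli`` mode).

The setting outputs follow a deterministic ground-truth rule plus Gaussian
noise:

    frequency    = b_f(disease) + 0.6 * (pCO2 - 40)            [breaths/min]
    tidal volume = b_v(disease) - 15 * (PEEP - 5)              [mL]
    FiO2         = 0.21 + 0.012 * sp(95 - pSO2)                [fraction]

where sp is a softened hinge (softplus), so FiO2 approaches room air
smoothly from above as saturation improves instead of hitting a hard floor.
A smooth rule matters: the learning-stage recovery guarantee requires the
target mapping to be representable by a tanh network, which a hard clamp
with a flat region is not.

The three output findings (frequency > 20, tidal volume < 400, FiO2 > 0.25)
must ALSO hit their prescribed frequencies, which a pure function of the
inputs cannot guarantee for every count pattern.  The generator therefore
applies one monotone continuous map per disease group and output: frequency
and tidal volume are translated by the constant placing exactly the required
number of patients beyond the binarization threshold (the cut sits midway
between the two straddling order statistics); FiO2 is scaled about its
0.21 room-air pivot, which achieves the same while never crossing the
physical floor.  Both maps preserve the shape of the rule — the realized
mapping stays continuous in the inputs and representable by the network —
while making the output-row frequencies exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .bayes import (
    DEFAULT_BINARIZATION,
    FINDING_NAMES,
    FindingTable,
    binarize_findings,
    load_reference_tables,
)
from .records import DISEASES, PatientRecord

#: Physiological input findings (everything except FiO2/frequency/tidal
#: volume, which are outputs, and the two mode rows).
INPUT_FINDINGS = (
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
)

OUTPUT_FINDINGS = ("fio2", "frequency", "tidal_volume")

#: Truncated-normal slices (mean, sd, low, high) for each finding's normal
#: band and abnormal band(s); bounds sit strictly inside the threshold so a
#: draw can never land on the wrong side.
_BANDS: dict[str, dict] = {
    "core_body_temperature": {
        "normal": (36.8, 0.5, 35.0, 37.4),
        "abnormal": [(38.5, 0.8, 37.6, 41.0)],
    },
    "pulse": {"normal": (82, 10, 50, 99.5), "abnormal": [(115, 12, 100.5, 170)]},
    "arterial_systolic_pressure": {
        "normal": (115, 12, 90.5, 139.5),
        "abnormal": [(80, 6, 55, 89.5), (155, 10, 140.5, 220)],
        "side_prob": 0.5,
    },
    "diastolic_blood_pressure": {
        "normal": (70, 10, 40, 89.5),
        "abnormal": [(100, 8, 90.5, 130)],
    },
    "peep": {"normal": (3.5, 1.0, 0.5, 4.9), "abnormal": [(12, 4, 5.5, 22)]},
    "pso2": {"normal": (96, 2.0, 90.5, 100), "abnormal": [(84, 5, 55, 89.5)]},
    "ph": {
        "normal": (7.40, 0.025, 7.351, 7.449),
        "abnormal": [(7.28, 0.04, 7.05, 7.34), (7.50, 0.03, 7.46, 7.70)],
        "side_prob": 0.7,
    },
    "po2": {"normal": (90, 8, 80.5, 120), "abnormal": [(62, 9, 35, 79.5)]},
    "pco2": {"normal": (38, 3, 28, 44.9), "abnormal": [(55, 8, 45.5, 90)]},
    "bicarbonate": {
        "normal": (24, 1.2, 22.1, 25.9),
        "abnormal": [(18, 2, 10, 21.5), (30, 2.5, 26.5, 40)],
        "side_prob": 0.5,
    },
}


@dataclass(frozen=True)
class GroundTruthRule:
    """Deterministic physiology-to-settings mapping used for target synthesis.

    Base rates/volumes are per disease; slopes tie the outputs to pCO2, PEEP
    and pSO2.  Defaults are clinically plausible artifact values.
    """

    base_frequency: Mapping[str, float] = field(
        default_factory=lambda: {"COPD": 18.0, "ARDS": 24.0, "CVD": 16.0}
    )
    base_tidal_volume: Mapping[str, float] = field(
        default_factory=lambda: {"COPD": 450.0, "ARDS": 380.0, "CVD": 480.0}
    )
    frequency_slope: float = 0.6  # breaths/min per mmHg pCO2 above 40
    tidal_slope: float = -15.0  # mL per cmH2O PEEP above 5
    fio2_slope: float = 0.012  # fraction per percent pSO2 below 95
    fio2_smoothing: float = 10.0  # softplus width, percent-saturation units

    def frequency(self, disease: str, pco2) -> np.ndarray | float:
        return self.base_frequency[disease] + self.frequency_slope * (
            np.asarray(pco2, dtype=float) - 40.0
        )

    def tidal_volume(self, disease: str, peep) -> np.ndarray | float:
        return self.base_tidal_volume[disease] + self.tidal_slope * (
            np.asarray(peep, dtype=float) - 5.0
        )

    def fio2(self, pso2) -> np.ndarray | float:
        """Smooth supplemental-oxygen demand; always strictly above 0.21."""
        deficit = 95.0 - np.asarray(pso2, dtype=float)
        w = self.fio2_smoothing
        sp = w * np.logaddexp(0.0, deficit / w)  # softplus, overflow-safe
        return np.minimum(0.21 + self.fio2_slope * sp, 1.0)


@dataclass(frozen=True)
class CohortSpec:
    """Conditions a synthetic cohort is generated under.

    ``exact_counts`` reproduces every finding count exactly; ``bernoulli``
    draws each finding independently with probability count/cohort_size.
    ``noise_scales`` are the Gaussian SDs added to (frequency, tidal volume,
    FiO2) before the count-exactness clamp.
    """

    sizes: Mapping[str, int] | None = None
    mode: str = "exact_counts"
    tables: Sequence[FindingTable] | None = None
    thresholds: Mapping | None = None
    rule: GroundTruthRule = field(default_factory=GroundTruthRule)
    noise_scales: tuple[float, float, float] = (1.5, 25.0, 0.03)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("exact_counts", "bernoulli"):
            raise ValueError(f"unknown generation mode {self.mode!r}")
        if self.sizes is not None and any(s <= 0 for s in self.sizes.values()):
            raise ValueError("group sizes must be positive")


def _draw_band(rng: np.random.Generator, band: tuple, size: int) -> np.ndarray:
    mean, sd, low, high = band
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _draw_values(
    rng: np.random.Generator, name: str, abnormal: np.ndarray
) -> np.ndarray:
    """Values for one finding given the per-patient abnormality flags."""
    spec = _BANDS[name]
    n = abnormal.size
    values = np.empty(n)
    normal_idx = np.flatnonzero(~abnormal)
    values[normal_idx] = _draw_band(rng, spec["normal"], normal_idx.size)
    ab_idx = np.flatnonzero(abnormal)
    bands = spec["abnormal"]
    if len(bands) == 1:
        values[ab_idx] = _draw_band(rng, bands[0], ab_idx.size)
    else:
        side = rng.random(ab_idx.size) < spec.get("side_prob", 0.5)
        lo_idx, hi_idx = ab_idx[side], ab_idx[~side]
        values[lo_idx] = _draw_band(rng, bands[0], lo_idx.size)
        values[hi_idx] = _draw_band(rng, bands[1], hi_idx.size)
    return values


def _select_abnormal(
    rng: np.random.Generator, n: int, count: int, probability: float, mode: str
) -> np.ndarray:
    if mode == "exact_counts":
        flags = np.zeros(n, dtype=bool)
        flags[rng.permutation(n)[:count]] = True
        return flags
    return rng.random(n) < probability


def _translate_to_count(
    values: np.ndarray,
    count: int,
    threshold: float,
    abnormal_high: bool,
    margin: float,
) -> np.ndarray:
    """Shift all values by the constant placing exactly ``count`` of them on
    the abnormal side of the threshold.

    The cut point sits midway between the count-th and (count+1)-th ranked
    values (or ``margin`` beyond the extremes when count is 0 or n), so the
    shifted values straddle the threshold strictly.
    """
    n = values.size
    if not 0 <= count <= n:
        raise ValueError("count must lie in [0, n]")
    ranked = np.sort(values)[::-1] if abnormal_high else np.sort(values)
    if count == 0:
        cut = ranked[0] + margin if abnormal_high else ranked[0] - margin
    elif count == n:
        cut = ranked[-1] - margin if abnormal_high else ranked[-1] + margin
    else:
        if ranked[count - 1] == ranked[count]:
            raise ValueError("tied output values cannot be separated by translation")
        cut = 0.5 * (ranked[count - 1] + ranked[count])
    return values + (threshold - cut)


def _scale_to_count(
    values: np.ndarray,
    count: int,
    threshold: float,
    pivot: float,
    margin: float,
) -> np.ndarray:
    """Scale values about ``pivot`` so exactly ``count`` exceed ``threshold``.

    Requires pivot < min(values) <= max(values) and pivot < threshold; the
    map v -> pivot + s*(v - pivot) is monotone and keeps every value above
    the pivot, so a physical floor just under the pivot is never crossed.
    """
    n = values.size
    if not 0 <= count <= n:
        raise ValueError("count must lie in [0, n]")
    ranked = np.sort(values)[::-1]
    if count == 0:
        cut = ranked[0] + margin
    elif count == n:
        cut = max(ranked[-1] - margin, 0.5 * (ranked[-1] + pivot))
    else:
        if ranked[count - 1] == ranked[count]:
            raise ValueError("tied output values cannot be separated by scaling")
        cut = 0.5 * (ranked[count - 1] + ranked[count])
    if cut <= pivot:
        raise ValueError("cut point collapsed onto the pivot")
    s = (threshold - pivot) / (cut - pivot)
    return pivot + s * (values - pivot)


def _generate_group(
    rng: np.random.Generator, disease: str, size: int, table: FindingTable, spec: CohortSpec
) -> list[PatientRecord]:
    counts = dict(zip(table.finding_names, table.counts))
    probs = dict(zip(table.finding_names, table.probabilities))
    if spec.mode == "exact_counts" and any(
        counts[f] > size for f in table.finding_names
    ):
        raise ValueError(
            f"{disease}: finding counts exceed group size {size} in exact_counts mode"
        )

    fields: dict[str, np.ndarray] = {}
    for name in INPUT_FINDINGS:
        abnormal = _select_abnormal(rng, size, counts[name], probs[name], spec.mode)
        fields[name] = _draw_values(rng, name, abnormal)

    # support mode: exactly (or on average) the pressure-support count
    if spec.mode == "exact_counts":
        ps = np.zeros(size, dtype=bool)
        ps[rng.permutation(size)[: counts["pressure_support"]]] = True
    else:
        ps = rng.random(size) < probs["pressure_support"]

    rule = spec.rule
    sd_f, sd_v, sd_o = spec.noise_scales
    freq = rule.frequency(disease, fields["pco2"]) + rng.normal(0.0, 1.0, size) * sd_f
    tv = rule.tidal_volume(disease, fields["peep"]) + rng.normal(0.0, 1.0, size) * sd_v
    fio2 = rule.fio2(fields["pso2"]) + rng.normal(0.0, 1.0, size) * sd_o
    fio2 = np.maximum(fio2, 0.21 + 1e-6)  # noise must not breach the pivot

    # output findings: one monotone continuous map per group places exactly
    # the required count on the abnormal side; final plausibility clamps lie
    # strictly on one side of each threshold, so counts survive them
    if spec.mode == "exact_counts":
        c_freq, c_tv, c_fio2 = (
            counts["frequency"],
            counts["tidal_volume"],
            counts["fio2"],
        )
    else:
        c_freq = int(rng.binomial(size, probs["frequency"]))
        c_tv = int(rng.binomial(size, probs["tidal_volume"]))
        c_fio2 = int(rng.binomial(size, probs["fio2"]))
    freq = np.clip(_translate_to_count(freq, c_freq, 20.0, True, 0.5), 4.0, 60.0)
    tv = np.clip(_translate_to_count(tv, c_tv, 400.0, False, 10.0), 100.0, 1200.0)
    fio2_out = np.clip(
        _scale_to_count(fio2, c_fio2, 0.25, 0.21, 0.01), 0.21, 1.0
    )

    records = []
    for i in range(size):
        records.append(
            PatientRecord(
                patient_id=f"{disease}-{i:03d}",
                disease=disease,
                core_body_temperature=float(fields["core_body_temperature"][i]),
                pulse=float(fields["pulse"][i]),
                arterial_systolic_pressure=float(
                    fields["arterial_systolic_pressure"][i]
                ),
                diastolic_blood_pressure=float(fields["diastolic_blood_pressure"][i]),
                peep=float(fields["peep"][i]),
                pso2=float(fields["pso2"][i]),
                ph=float(fields["ph"][i]),
                po2=float(fields["po2"][i]),
                pco2=float(fields["pco2"][i]),
                bicarbonate=float(fields["bicarbonate"][i]),
                frequency=float(freq[i]),
                tidal_volume=float(tv[i]),
                fio2=float(fio2_out[i]),
                support_mode="PS" if ps[i] else "VS",
            )
        )
    return records


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Generate a labeled synthetic cohort under the given conditions.

    Deterministic per seed; group order is COPD, ARDS, CVD.
    """
    tables = list(spec.tables) if spec.tables is not None else load_reference_tables()
    by_disease = {t.disease: t for t in tables}
    sizes = (
        dict(spec.sizes)
        if spec.sizes is not None
        else {d: by_disease[d].cohort_size for d in DISEASES}
    )
    rng = np.random.default_rng(spec.seed)
    cohort: list[PatientRecord] = []
    for disease in DISEASES:
        cohort.extend(
            _generate_group(rng, disease, sizes[disease], by_disease[disease], spec)
        )
    return cohort


def cohort_to_finding_tables(
    records: Sequence[PatientRecord], thresholds: Mapping | None = None
) -> list[FindingTable]:
    """Tally binarized findings per disease — the inverse of exact-count
    generation."""
    if thresholds is None:
        thresholds = DEFAULT_BINARIZATION
    groups: dict[str, list[PatientRecord]] = {d: [] for d in DISEASES}
    for rec in records:
        if rec.disease is None:
            raise ValueError(f"record {rec.patient_id!r} has no disease label")
        groups[rec.disease].append(rec)
    tables = []
    for disease in DISEASES:
        members = groups[disease]
        if not members:
            raise ValueError(f"no records for disease {disease}")
        counts = np.zeros(len(FINDING_NAMES), dtype=int)
        for rec in members:
            presence = binarize_findings(rec, thresholds)
            counts += np.asarray(presence.flags, dtype=int)
        tables.append(
            FindingTable(
                disease=disease,
                cohort_size=len(members),
                counts=tuple(int(c) for c in counts),
            )
        )
    return tables
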