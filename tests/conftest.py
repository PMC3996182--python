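import pytest

from ventdss.bayes import load_reference_tables
from ventdss.records import PatientRecord
from ventdss.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def reference_tables():
    return load_reference_tables()


@pytest.fixture(scope="session")
def cohort158():
    """Default exact-counts synthetic cohort (30 COPD / 65 ARDS / 63 CVD)."""
    return generate_cohort(CohortSpec(seed=1))


@pytest.fixture(scope="session")
def noisefree_cohort():
    return generate_cohort(CohortSpec(seed=3, noise_scales=(0.0, 0.0, 0.0)))


@pytest.fixture
def normal_record():
    """A fully populated record with unremarkable physiology."""
    return PatientRecord(
        patient_id="p1",
        disease="COPD",
        core_body_temperature=36.8,
        pulse=80.0,
        arterial_systolic_pressure=120.0,
        diastolic_blood_pressure=75.0,
        peep=4.0,
        pso2=96.0,
        ph=7.40,
        po2=92.0,
        pco2=40.0,
        bicarbonate=24.0,
        frequency=14.0,
        tidal_volume=500.0,
        fio2=0.21,
        support_mode="PS",
    )
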