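import numpy as np
import pytest

from eppm import PatientRecord, default_config, default_rules, generate_cohort


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture
def example_patient():
    """The worked-example patient of the published grading rules: 46 years,
    temporal lobe, GCS 8, ε4 carrier, CRP 14.2 mg/L, IL-8 15.20 pg/mL,
    Marshall class III."""
    return PatientRecord(
        patient_id="example",
        age=46,
        sex="male",
        mechanism="traffic",
        damaged_area="temporal",
        gcs=8,
        apoe_e4_carrier=True,
        crp=14.2,
        il8=15.20,
        marshall="III",
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic 60-patient synthetic cohort with outcome labels."""
    return generate_cohort(default_config(n=60, seed=11))


@pytest.fixture(scope="session")
def training_cohort():
    """Deterministic 300-patient synthetic training cohort."""
    return generate_cohort(default_config(n=300, seed=23))


def random_valid_record(rng: np.random.Generator, i: int = 0) -> PatientRecord:
    """Draw a uniformly random valid patient record (no outcome structure)."""
    return PatientRecord(
        patient_id=f"R{i}",
        age=int(rng.integers(15, 76)),
        sex=str(rng.choice(["male", "female"])),
        mechanism=str(rng.choice(["traffic", "striking", "fall", "other"])),
        damaged_area=str(rng.choice(["frontal", "temporal", "parietal", "occipital"])),
        gcs=int(rng.integers(3, 16)),
        apoe_e4_carrier=bool(rng.integers(0, 2)),
        crp=float(rng.uniform(0, 40)),
        il8=float(rng.uniform(0, 50)),
        marshall=str(rng.choice(["I", "II", "III", "IV", "V", "VI"])),
        outcome=str(rng.choice(["poor", "good"])),
    )
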