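import pytest

from fuzzyheart import DiagnosisSystem, PatientRecord, load_variables


@pytest.fixture(scope="session")
def model():
    return load_variables()


@pytest.fixture(scope="session")
def system(model):
    """Full pipeline with the generated 4320-rule knowledge base."""
    return DiagnosisSystem(model=model)


@pytest.fixture(scope="session")
def rulebase(system):
    return system.rulebase


@pytest.fixture()
def reference_record():
    """The published diagnostic test case: atypical chest pain, high
    HbA1c, low HDL, very-high LDL, resting heart rate, mid age, and
    blood pressure on the Normal/High overlap."""
    return PatientRecord(chest_pain=5, hba1c=10, hdl=30, ldl=141,
                         heart_rate=60, age=59, blood_pressure=126)
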