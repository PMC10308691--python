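import numpy as np
import pytest

from longewas import preprocess, simcohort
from longewas.glycemia import GlucoseProfile
from longewas.simcohort import SimulationConfig, SubjectRecord


def make_subject(
    sid="S0000",
    glucose=(4.2, 7.1, 5.7),
    maternal_age=28.0,
    bmi=24.0,
    gravidity=False,
    smoking=False,
    girl=True,
    has_birth=True,
    has_5y=True,
) -> SubjectRecord:
    return SubjectRecord(
        subject_id=sid,
        maternal_age=maternal_age,
        bmi_t1=bmi,
        gravidity=gravidity,
        smoking=smoking,
        child_sex=girl,
        glucose=GlucoseProfile(values=glucose),
        gestational_age_birth=39.5,
        child_age_5y=5.2,
        has_birth_sample=has_birth,
        has_5y_sample=has_5y,
    )


@pytest.fixture(scope="session")
def small_sim():
    """A modest synthetic study shared across unit tests (400 CpGs)."""
    return simcohort.simulate_study(SimulationConfig(n_cpgs=400, n_causal=20, seed=11))


@pytest.fixture(scope="session")
def small_prep(small_sim):
    return preprocess.preprocess_study(small_sim.study, small_sim.panels)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
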