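import numpy as np
import pytest

from crcaware.experiments import ModelInputs, _evaluate
from crcaware.parameters import ModelParameters
from crcaware.screening import ScreeningProgramme
from crcaware.synthetic_data import (
    Demography,
    make_demography_fixture,
    make_survival_fixture,
)


@pytest.fixture(scope="session")
def inputs() -> ModelInputs:
    """Default England-like inputs with screening enabled."""
    return ModelInputs()


@pytest.fixture(scope="session")
def base_eval(inputs):
    """No-campaign evaluation shared across tests (deterministic)."""
    return _evaluate(inputs, None)


@pytest.fixture(scope="session")
def campaign_eval(inputs):
    """Base-case campaign evaluation shared across tests."""
    return _evaluate(inputs, inputs.params.campaign)


@pytest.fixture(scope="session")
def no_screening_inputs() -> ModelInputs:
    return ModelInputs(
        programme=ScreeningProgramme(enabled=False),
    )


@pytest.fixture
def single_cohort_demography() -> Demography:
    """One person aged 40; every other cohort empty."""
    demo = make_demography_fixture(1000, "uniform")
    pop = np.zeros_like(demo.population)
    pop[40 - 30] = 1.0
    return Demography(
        ages=demo.ages, population=pop, all_cause_mortality=demo.all_cause_mortality
    )


@pytest.fixture(scope="session")
def survival():
    return make_survival_fixture("default")


@pytest.fixture(scope="session")
def null_survival():
    return make_survival_fixture("null")


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()
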