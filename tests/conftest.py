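import pytest

from pedrenal.physiology import individual, load_individuals, system_parameters
from pedrenal.study import RunConfig, run_study


@pytest.fixture(scope="session")
def individuals():
    return load_individuals()


@pytest.fixture(scope="session")
def adult():
    return individual("Adult")


@pytest.fixture(scope="session")
def adult_sys(adult):
    return system_parameters(adult)


@pytest.fixture(scope="session")
def study_tables():
    """One full default study run shared by the integration-level tests."""
    return run_study(RunConfig())
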