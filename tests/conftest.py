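import pytest

from sbrtlc.cohort import impute_diameters, load_table1_fixture, simulate_plans
from sbrtlc.lq import FractionScheme, P110, P120
from sbrtlc.models import ModelLibrary

STANDARD_SCHEMES = ["1x30", "3x15", "4x12", "3x18", "5x10"]


@pytest.fixture(scope="session")
def fixture_cohort():
    """The bundled 17-patient cohort, diameters absent."""
    return load_table1_fixture()


@pytest.fixture(scope="session")
def cohort_with_diameters(fixture_cohort):
    """Fixture cohort with seeded synthetic diameters imputed."""
    return impute_diameters(fixture_cohort, seed=7)


@pytest.fixture(scope="session")
def schemes():
    return [FractionScheme.from_string(s) for s in STANDARD_SCHEMES]


@pytest.fixture(scope="session")
def library():
    return ModelLibrary()


@pytest.fixture(scope="session")
def nominal_plans(cohort_with_diameters, schemes):
    """Plans for both scenarios with zero jitter: achieved factor is exactly
    the nominal 1.10 / 1.20."""
    plans = simulate_plans(cohort_with_diameters, schemes, P110, jitter_halfwidth=0.0, seed=1)
    plans += simulate_plans(cohort_with_diameters, schemes, P120, jitter_halfwidth=0.0, seed=2)
    return plans
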