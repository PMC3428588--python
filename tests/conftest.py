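import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from brainbehavior import GridSpec, assemble_pdf4d, known_answer_suite

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

SUITE_SEED = 7


@pytest.fixture(scope="session")
def suite():
    """Canonical synthetic fixtures with known qualitative outcomes."""
    return known_answer_suite(SUITE_SEED)


@pytest.fixture(scope="session")
def recovery_pdf(suite):
    return assemble_pdf4d(suite.recovery.foci, suite.grid)


@pytest.fixture(scope="session")
def disjoint_pdf(suite):
    return assemble_pdf4d(suite.disjoint.foci, suite.grid)


@pytest.fixture()
def toy_grid():
    """A 6x6x6 grid with 2-mm spacing for hand-checkable cases."""
    return GridSpec(2.0, (-4.0, -6.0, -4.0), (6, 6, 6))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
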