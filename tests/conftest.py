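import numpy as np
import pytest

from isogx.simulate import CohortDesign, generate_annotations, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort shared across read-only tests."""
    return generate_cohort(CohortDesign(seed=11))


@pytest.fixture(scope="session")
def annotations():
    return generate_annotations(CohortDesign(seed=5), np.random.default_rng(5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
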