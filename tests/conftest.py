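import numpy as np
import pytest

from chemonet import synthetic


@pytest.fixture(scope="session")
def default_design():
    return synthetic.SimulationDesign(seed=11)


@pytest.fixture(scope="session")
def study(default_design):
    """Two sibling cohorts of the default design, tumors + matched normals."""
    return synthetic.simulate_study(default_design)


@pytest.fixture(scope="session")
def tumor_cohort(study):
    cohort = study[0].cohort
    return cohort.subset_samples(cohort.tumor_samples())


@pytest.fixture(scope="session")
def truth(study):
    return study[0].truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
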