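import numpy as np
import pytest

from transomics import build_design, simulate_counts, simulate_metabolites


@pytest.fixture(scope="session")
def design1():
    return build_design(1)


@pytest.fixture(scope="session")
def design3():
    return build_design(3)


@pytest.fixture(scope="session")
def sim_counts_small(design3):
    return simulate_counts(design3, n_features=300, seed=42)


@pytest.fixture(scope="session")
def sim_metab_small(design3):
    return simulate_metabolites(design3, n_rois=120, seed=42)


@pytest.fixture(scope="session")
def balanced_fractions():
    return {
        "circadian": 0.2,
        "fasting_low": 0.2,
        "gradual": 0.2,
        "feeding_acute": 0.2,
        "null": 0.2,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
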