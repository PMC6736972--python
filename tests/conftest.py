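import numpy as np
import pytest

import painmediate as pm
from painmediate.synthetic import BrainParams


@pytest.fixture(scope="session")
def small_design():
    """12-subject default-structure design (96 trials, 6 runs)."""
    return pm.generate_design(pm.DesignConfig(n_subjects=12, rng_seed=7))


@pytest.fixture(scope="session")
def small_behavior(small_design):
    return pm.generate_behavior(small_design, seed=11)


@pytest.fixture(scope="session")
def small_brain(small_behavior):
    """12 subjects on a 12^3 grid with 60-voxel planted populations."""
    params = BrainParams(shape=(12, 12, 12), n_social=60, n_cs=60, n_pain=60)
    return pm.generate_brain(small_behavior, params, seed=13)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
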