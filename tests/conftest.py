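import numpy as np
import pytest

from cermorph.atlas_io import split_atlas_left_right
from cermorph.synthetic_cohort import (
    CohortConfig,
    generate_atlas,
    generate_probability_map,
)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale cohort conditions for unit tests (24x24x20 grid)."""
    return CohortConfig(
        n_subjects=8,
        n_positive=2,
        grid_shape=(24, 24, 20),
        noise_sd=4.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_atlas(small_config):
    return generate_atlas(small_config)


@pytest.fixture(scope="session")
def small_split_atlas(small_config):
    return split_atlas_left_right(generate_atlas(small_config))


@pytest.fixture(scope="session")
def small_pmap(small_config):
    return generate_probability_map(small_config)


@pytest.fixture(scope="session")
def reg_config():
    """Mid-size grid for registration recovery tests."""
    return CohortConfig(grid_shape=(32, 32, 28), seed=3)


@pytest.fixture(scope="session")
def reg_atlas(reg_config):
    return generate_atlas(reg_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
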