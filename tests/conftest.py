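import numpy as np
import pytest
from dataclasses import replace

from canopygrowth.synthetic import (
    default_config,
    generate_field_dataset,
    generate_trait_table,
)


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def cfg_unmasked(cfg):
    return replace(cfg, mask_sa=False)


@pytest.fixture(scope="session")
def traits43(cfg_unmasked):
    """One 43-tree trait table with fully observed sapwood area."""
    traits, truth = generate_trait_table(cfg_unmasked, seed=707, n_scale=1)
    return traits, truth


@pytest.fixture(scope="session")
def traits430(cfg_unmasked):
    """A 430-tree trait table (the recovery-harness population size)."""
    traits, truth = generate_trait_table(cfg_unmasked, seed=430, n_scale=10)
    return traits, truth


@pytest.fixture(scope="session")
def field43(cfg):
    """43 synthetic trees as raw field measurements (Cariniana SA masked)."""
    trees, traits, truth = generate_field_dataset(cfg, seed=9, n_scale=1)
    return trees, traits, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
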