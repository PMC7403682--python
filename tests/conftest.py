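import numpy as np
import pytest

from ecotensor.synthdata import SimConfig, simulate_pedigree


def small_sim_config(**overrides) -> SimConfig:
    """A fast, fully-featured crossing design for unit tests."""
    base = dict(
        n_parents_per_ecotype=10,
        f1_families_per_cross=(3, 4),
        f2_families_per_cross=(2, 3),
        n_f3_families=45,
        n_f4_families=30,
        p_field_families_per_ecotype=8,
        f1_field_families_per_cross=3,
        seeds_per_family_habitat={"P": 4, "F1": 4, "F4": 6},
        rng_seed=11,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_config():
    return small_sim_config()


@pytest.fixture(scope="session")
def small_pedigree(small_config):
    return simulate_pedigree(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
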