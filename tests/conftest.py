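import numpy as np
import pytest

from morphoclass.synthetic import (
    CLASS_NAMES,
    SyntheticConfig,
    generate_world,
    simulate_chip_counts,
)


@pytest.fixture(scope="session")
def tiny_config() -> SyntheticConfig:
    """A small world: 4 x 15 peaks on two short chromosomes."""
    return SyntheticConfig(
        seed=5,
        n_peaks={k: 15 for k in CLASS_NAMES},
        n_noise_regions=200,
        n_background_regions=150,
        chrom_lengths={"chr2L": 2_000_000, "chrX": 1_500_000},
        n_extra_tiles=30,
        n_extra_tss=50,
    )


@pytest.fixture(scope="session")
def tiny_world(tiny_config):
    return generate_world(tiny_config)


@pytest.fixture(scope="session")
def tiny_chip(tiny_world):
    return simulate_chip_counts(tiny_world)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
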