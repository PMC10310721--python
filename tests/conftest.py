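import numpy as np
import pytest

from predniche import synthetic
from predniche.synthetic import SimConfig


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Two large classes so the <100-species class filter keeps everything."""
    return SimConfig(
        n_species=400,
        seed=7,
        class_weights={"Aves": 0.55, "Mammalia": 0.45},
        grid_dims=(15, 20),
    )


@pytest.fixture(scope="session")
def small_records(small_cfg):
    return synthetic.generate_species_table(small_cfg)


@pytest.fixture(scope="session")
def small_tree(small_cfg, small_records):
    return synthetic.generate_phylogeny(
        small_cfg.n_species, small_cfg.seed,
        tip_names=[r.binomial for r in small_records],
    )


@pytest.fixture(scope="session")
def small_ranges(small_cfg, small_records):
    return synthetic.generate_ranges(small_records, small_cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
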