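import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from sexlink.synthetic import GenusModel, star_tree, simulate_genus


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def zero_div_genus():
    """3 species, zero divergence, one 2 kb Y block, no hermaphrodite."""
    model = GenusModel(
        species_tree=star_tree(3, 0.0),
        n_species=3,
        autosome_length=20_000,
        xy_shared_length=5_000,
        y_specific_blocks=[("blk", 2_000)],
        with_hermaphrodite=False,
        seed=7,
    )
    return simulate_genus(model, k=16)


@pytest.fixture(scope="session")
def small_genus():
    """4 diverged species with hermaphrodite control, desk scale."""
    model = GenusModel.default(
        n_species=4, autosome_length=30_000, xy_shared_length=6_000,
        y_block_length=3_000, seed=11,
    )
    return simulate_genus(model, k=16)
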