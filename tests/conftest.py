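import numpy as np
import pytest

from netscreen.synthetic import SyntheticConfig, generate_all


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic study at the documented defaults (seed 0)."""
    return generate_all(SyntheticConfig(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A scaled-down config for fast structural checks."""
    return SyntheticConfig(
        seed=7,
        n_nodes=120,
        planted_clique_sizes=(6,),
        n_genes=40,
        n_cells_per_condition=400,
        n_drugs=10,
    )
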