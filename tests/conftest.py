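import numpy as np
import pytest

from utrscape import PanelConfig, gen_panel


@pytest.fixture(scope="session")
def small_panel():
    """A 4-species, 120-gene panel shared by read-only tests."""
    return gen_panel(PanelConfig(n_species=4, n_genes=120, n_tissues=10, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
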