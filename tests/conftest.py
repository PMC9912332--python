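import pytest

from lnpscreen import ScreenSimConfig, ScSimConfig, default_library
from lnpscreen.synth import simulate_sc_matrix, simulate_screen_counts


@pytest.fixture(scope="session")
def lib():
    """The default 144-design library (137 pooled), barcodes under seed 0."""
    return default_library(seed=0)


@pytest.fixture(scope="session")
def screen(lib):
    """One default 4-mouse, 19-cell-type screen simulation."""
    return simulate_screen_counts(ScreenSimConfig(library=lib, seed=1))


@pytest.fixture(scope="session")
def sc_data():
    """Default single-cell simulation: 8 clusters x 4 groups x 150 cells,
    1200 genes + aVHH, 15 genes planted at log2fc=2 in Cat-LNP."""
    return simulate_sc_matrix(ScSimConfig(seed=5))
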