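import numpy as np
import pytest

import embryochron as ec


@pytest.fixture(scope="session")
def small_atlas():
    """A small but fully structured atlas shared by fast unit tests."""
    cfg = ec.AtlasConfig(cells_per_window_rna=60, cells_per_window_atac=40,
                         n_genes=80, n_background_peaks=40,
                         lineage_tree=ec.binary_lineage_tree((1, 2),
                                                             (0.0, 8.0, 20.0)),
                         n_tfs=6)
    return ec.simulate_atlas(cfg, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
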