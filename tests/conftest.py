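import numpy as np
import pytest

import tanypsa as tp
from tanypsa.pipeline import default_anchor_genes


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced planted dataset shared by unit tests (fast, still structured)."""
    cfg = tp.default_config(seed=1, n_cells_per_condition=300, n_genes=1200)
    adata, gt = tp.generate_dataset(cfg)
    return adata, gt


@pytest.fixture(scope="session")
def small_norm(small_dataset):
    adata, gt = small_dataset
    filtered, _ = tp.qc_filter(adata)
    return tp.normalize(filtered), gt


@pytest.fixture(scope="session")
def default_dataset():
    """The full-scale planted design (3 conditions x 1500 cells, 2000 genes)."""
    cfg = tp.default_config(seed=1)
    adata, gt = tp.generate_dataset(cfg)
    return adata, gt


@pytest.fixture(scope="session")
def default_norm(default_dataset):
    adata, gt = default_dataset
    filtered, _ = tp.qc_filter(adata)
    return tp.normalize(filtered), gt


@pytest.fixture(scope="session")
def default_pseudospace(default_norm):
    norm, gt = default_norm
    ps = tp.order_cells(norm, default_anchor_genes(norm))
    return ps


@pytest.fixture(scope="session")
def default_profiles(default_norm, default_pseudospace):
    norm, _ = default_norm
    return tp.fit_profiles(norm, default_pseudospace)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
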