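import numpy as np
import pytest
import scipy.sparse as sp

from spatialflow.preprocess import STDataset
from spatialflow.synthetic import simulate_layered_tissue


@pytest.fixture(scope="session")
def layered_tissue():
    """Default layered tissue (3 layers x 200 cells, 300 genes)."""
    return simulate_layered_tissue(seed=0)


@pytest.fixture(scope="session")
def small_tissue():
    """Small layered tissue for fast training tests."""
    return simulate_layered_tissue(
        n_layers=3, cells_per_layer=40, n_genes=120, n_markers_per_layer=10,
        seed=0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_dataset(rng, n_cells=30, n_genes=20, density=0.6):
    counts = sp.random(
        n_cells, n_genes, density=density, random_state=np.random.RandomState(7),
        data_rvs=lambda k: rng.integers(1, 10, size=k),
    )
    return STDataset(
        counts=sp.csr_matrix(counts, dtype=np.int64),
        coords=rng.uniform(0, 10, size=(n_cells, 2)),
        cell_ids=np.array([f"c{i}" for i in range(n_cells)], dtype=object),
        gene_ids=np.array([f"g{j}" for j in range(n_genes)], dtype=object),
    )
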