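import numpy as np
import pytest

from spatialtme import SimulationConfig, SpotDataset, simulate_dataset, tp10k_normalize
from spatialtme.graph import grid_graph_from_coords


def make_dataset(counts, coords=None, normalize=True, genes=None, barcodes=None):
    """Small in-memory dataset for unit tests."""
    counts = np.asarray(counts)
    n, p = counts.shape
    if coords is None:
        coords = [(i, 0) for i in range(n)]
    ds = SpotDataset(
        counts=counts,
        coords=np.asarray(coords, dtype=int),
        barcodes=barcodes or [f"s{i}" for i in range(n)],
        genes=genes or [f"g{j}" for j in range(p)],
    )
    return tp10k_normalize(ds) if normalize else ds


def full_grid(rows, cols, adjacency="rook"):
    """Graph over a fully occupied rows x cols grid."""
    coords = np.array([(x, y) for y in range(rows) for x in range(cols)])
    names = [f"s{x}_{y}" for x, y in coords]
    return grid_graph_from_coords(coords, names, adjacency=adjacency)


def path_graph(n=4):
    """n spots in a row under rook adjacency: a simple path."""
    return full_grid(1, n, adjacency="rook")


def moran_double_loop(x, W, n_nodes):
    """Independent O(N^2) evaluation of the Moran formula."""
    x = np.asarray(x, float)
    W = np.asarray(W, float)
    xbar = x.mean()
    num = 0.0
    for i in range(n_nodes):
        for j in range(n_nodes):
            num += W[i, j] * (x[i] - xbar) * (x[j] - xbar)
    den = ((x - xbar) ** 2).sum()
    return (n_nodes / W.sum()) * num / den


@pytest.fixture(scope="session")
def sample():
    """One default-condition synthetic sample shared across tests."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_sample():
    """Smaller, faster sample for plumbing tests."""
    return simulate_dataset(
        SimulationConfig(seed=7, grid_rows=14, grid_cols=14, background_genes=120)
    )
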