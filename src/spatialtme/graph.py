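"""Neighborhood connectivity graphs over occupied array spots.

Nodes are occupied spots; edges connect spatially adjacent spots with equal
weight.  Empty grid positions break adjacency: two occupied spots separated
by an empty position (offset 2 along an axis) are never connected — grid
adjacency is strictly offset-1.  The graph exposes the two weight matrices
downstream statistics need: the binary symmetric matrix ``W_binary`` (used
by Moran's I, where every edge has equal weight) and the row-standardized
``W_row`` (used by spatial PCA and the spatial-lag model, whose parameter
space requires row sums of one).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix, diags
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial import Delaunay, QhullError, cKDTree

from .io import SpotDataset

logger = logging.getLogger(__name__)

__all__ = [
    "NeighborGraph",
    "build_grid_graph",
    "grid_graph_from_coords",
    "build_delaunay_graph",
    "build_radius_graph",
    "hop_distances",
]

_ROOK_OFFSETS = [(1, 0), (-1, 0), (0, 1), (0, -1)]
_QUEEN_OFFSETS = _ROOK_OFFSETS + [(1, 1), (1, -1), (-1, 1), (-1, -1)]


@dataclass
class NeighborGraph:
    """Connectivity graph over occupied spots.

    Attributes
    ----------
    nodes : spot barcodes, defining the row/column order of all matrices.
    coords : (n, 2) grid coordinates aligned to ``nodes``.
    edges : (m, 2) int array of node-index pairs (i < j), each unordered pair
        listed once.
    scheme : how the graph was built ("grid-rook", "grid-queen", "radius",
        "delaunay").
    """

    nodes: list[str]
    coords: np.ndarray
    edges: np.ndarray
    scheme: str = "grid-queen"
    _hop: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords)
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        n = len(self.nodes)
        degree = np.zeros(n, dtype=int)
        for i, j in self.edges:
            degree[i] += 1
            degree[j] += 1
        n_isolated = int((degree == 0).sum())
        if n_isolated:
            logger.warning("%d isolated node(s) retained in the graph", n_isolated)
        logger.info(
            "graph: %d nodes, %d edges, %d connected component(s)",
            n, len(self.edges), self.n_components,
        )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def W_binary(self) -> csr_matrix:
        """Symmetric 0/1 weight matrix with zero diagonal."""
        n = self.n_nodes
        if self.n_edges == 0:
            return csr_matrix((n, n))
        i, j = self.edges[:, 0], self.edges[:, 1]
        rows = np.concatenate([i, j])
        cols = np.concatenate([j, i])
        data = np.ones(len(rows))
        return csr_matrix((data, (rows, cols)), shape=(n, n))

    @property
    def W_row(self) -> csr_matrix:
        """Row-standardized weights; zero rows stay zero for isolated nodes."""
        W = self.W_binary.tocsr(copy=True)
        rowsum = np.asarray(W.sum(axis=1)).ravel()
        scale = np.divide(1.0, rowsum, out=np.zeros_like(rowsum), where=rowsum > 0)
        return csr_matrix(diags(scale) @ W)

    @property
    def W_total(self) -> float:
        """Sum of all binary weights (twice the edge count)."""
        return 2.0 * self.n_edges

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.W_binary.sum(axis=1)).ravel().astype(int)

    @property
    def n_components(self) -> int:
        n_comp, _ = connected_components(self.W_binary, directed=False)
        return int(n_comp)

    def component_labels(self) -> np.ndarray:
        _, labels = connected_components(self.W_binary, directed=False)
        return labels

    def largest_component_fraction(self) -> float:
        labels = self.component_labels()
        return np.bincount(labels).max() / self.n_nodes

    def hop_distances(self) -> np.ndarray:
        """Shortest-path edge counts between all node pairs (inf across components)."""
        if self._hop is None:
            self._hop = shortest_path(self.W_binary, method="D", unweighted=True)
        return self._hop

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for idx, name in enumerate(self.nodes):
            g.add_node(name, x=int(self.coords[idx, 0]), y=int(self.coords[idx, 1]))
        g.add_edges_from((self.nodes[i], self.nodes[j]) for i, j in self.edges)
        return g

    def write_edge_list(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("source\ttarget\n")
            for i, j in self.edges:
                fh.write(f"{self.nodes[i]}\t{self.nodes[j]}\n")


def _edges_from_pairs(pairs) -> np.ndarray:
    if len(pairs) == 0:
        return np.empty((0, 2), dtype=int)
    arr = np.array(sorted({(min(i, j), max(i, j)) for i, j in pairs}), dtype=int)
    return arr


def build_grid_graph(dataset: SpotDataset, adjacency: str = "queen") -> NeighborGraph:
    """Connect occupied spots at unit grid offsets.

    ``rook`` uses the 4 axis neighbors, ``queen`` adds the 4 diagonals.
    Because adjacency is strictly offset-1 among occupied spots, a pair of
    occupied spots with an empty position between them is not connected.
    """
    return grid_graph_from_coords(dataset.coords, list(dataset.barcodes), adjacency)


def grid_graph_from_coords(coords, barcodes: list[str], adjacency: str = "queen") -> NeighborGraph:
    """Grid graph directly from integer coordinates (no counts required)."""
    coords = np.asarray(coords, dtype=int)
    if len(coords) < 2:
        raise ValueError("need at least 2 occupied spots to build a graph")
    if adjacency == "rook":
        offsets = _ROOK_OFFSETS
    elif adjacency == "queen":
        offsets = _QUEEN_OFFSETS
    else:
        raise ValueError(f"adjacency must be 'rook' or 'queen', got {adjacency!r}")
    index = {(int(x), int(y)): i for i, (x, y) in enumerate(coords)}
    pairs = []
    for (x, y), i in index.items():
        for dx, dy in offsets:
            j = index.get((x + dx, y + dy))
            if j is not None and j > i:
                pairs.append((i, j))
    return NeighborGraph(
        nodes=list(barcodes),
        coords=coords.copy(),
        edges=_edges_from_pairs(pairs),
        scheme=f"grid-{adjacency}",
    )


def build_radius_graph(dataset: SpotDataset, radius: float) -> NeighborGraph:
    """Connect spot pairs within Euclidean distance ``radius`` (inclusive)."""
    if dataset.n_spots < 2:
        raise ValueError("need at least 2 occupied spots to build a graph")
    tree = cKDTree(dataset.coords.astype(float))
    pairs = tree.query_pairs(r=radius + 1e-9)
    return NeighborGraph(
        nodes=list(dataset.barcodes),
        coords=dataset.coords.copy(),
        edges=_edges_from_pairs(pairs),
        scheme="radius",
    )


def build_delaunay_graph(dataset: SpotDataset, max_edge_len: float = np.inf) -> NeighborGraph:
    """Delaunay triangulation edges, pruned at ``max_edge_len``.

    Collinear input (no valid triangulation) falls back to a radius graph
    with radius ``max_edge_len``, with a warning.
    """
    if dataset.n_spots < 3:
        raise ValueError("Delaunay triangulation needs at least 3 spots")
    pts = dataset.coords.astype(float)
    try:
        tri = Delaunay(pts)
    except QhullError:
        logger.warning("collinear input: falling back to radius graph")
        return build_radius_graph(dataset, radius=max_edge_len)
    pairs = set()
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                i, j = int(simplex[a]), int(simplex[b])
                if np.linalg.norm(pts[i] - pts[j]) <= max_edge_len:
                    pairs.add((min(i, j), max(i, j)))
    return NeighborGraph(
        nodes=list(dataset.barcodes),
        coords=dataset.coords.copy(),
        edges=_edges_from_pairs(pairs),
        scheme="delaunay",
    )


def hop_distances(graph: NeighborGraph) -> np.ndarray:
    """Breadth-first shortest-path edge counts (module-level convenience)."""
    return graph.hop_distances()
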