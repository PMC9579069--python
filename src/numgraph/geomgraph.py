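"""Random geometric graphs on point configurations.

``G_d`` has an edge between two points iff their Euclidean distance is at
most the connectivity distance ``d`` (closed threshold: the boundary case has
probability zero for continuous coordinates, and the closed rule matches the
tangency convention of the occupancy model, where regions of influence of
radius d/2 touch exactly at separation d).

Graphs are kept as dense boolean adjacency matrices — at stimulus scale
(n <= a few hundred) O(n^2) construction is instantaneous and a spatial index
would only add moving parts.  ``G_d`` is monotone in d: for d1 <= d2 every
edge of G_{d1} is an edge of G_{d2}, which the distance sweep relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _cc

from .stimgen import PointConfiguration

__all__ = ["GeometricGraph", "build_graph", "degree_sequence", "components", "export_edges_csv"]


@dataclass(frozen=True)
class GeometricGraph:
    """The geometric graph G_d of a point configuration at distance d."""

    adjacency: np.ndarray  # (n, n) bool, symmetric, zero diagonal
    d: float
    source: PointConfiguration

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def edges(self) -> np.ndarray:
        """Edge list as an (m, 2) array of vertex index pairs i < j."""
        iu = np.triu_indices(self.n, k=1)
        mask = self.adjacency[iu]
        return np.column_stack((iu[0][mask], iu[1][mask]))

    @property
    def edge_lengths(self) -> np.ndarray:
        dm = self.source.distance_matrix()
        iu = np.triu_indices(self.n, k=1)
        mask = self.adjacency[iu]
        return dm[iu][mask]

    @property
    def edge_count(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(map(tuple, self.edges))
        return g


def build_graph(config: PointConfiguration, d: float, _dist: np.ndarray | None = None) -> GeometricGraph:
    """Construct G_d: edge (i, j) present iff dist(i, j) <= d.

    ``_dist`` lets callers that sweep many d values on one configuration
    reuse a precomputed distance matrix.
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    dm = config.distance_matrix() if _dist is None else _dist
    adj = dm <= d
    np.fill_diagonal(adj, False)
    return GeometricGraph(adjacency=adj, d=float(d), source=config)


def degree_sequence(g: GeometricGraph) -> np.ndarray:
    """Per-vertex degrees; sums to twice the edge count."""
    return g.degrees()


def components(g: GeometricGraph) -> list[list[int]]:
    """Partition of the vertex set into maximal connected subsets."""
    ncomp, labels = _cc(csr_matrix(g.adjacency), directed=False)
    return [list(np.flatnonzero(labels == k)) for k in range(ncomp)]


def n_components(g: GeometricGraph) -> int:
    ncomp, _ = _cc(csr_matrix(g.adjacency), directed=False)
    return int(ncomp)


def is_connected(g: GeometricGraph) -> bool:
    return n_components(g) == 1


def export_edges_csv(graphs: Iterable[GeometricGraph], path: str | Path) -> None:
    """Edge lists as tidy CSV: pattern_id, d, i, j, length."""
    rows = []
    for g in graphs:
        lengths = g.edge_lengths
        for (i, j), ln in zip(g.edges, lengths):
            rows.append({"pattern_id": g.source.pattern_id, "d": g.d, "i": int(i), "j": int(j), "length": ln})
    pd.DataFrame(rows, columns=["pattern_id", "d", "i", "j", "length"]).to_csv(path, index=False)
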