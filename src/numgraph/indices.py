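"""The ten normalized graph indices.

Every index is normalized so that, for the seven combinatorial indices, the
value lies in [0, 1] for any graph:

======  ==========================================================
TD      graph density, 2|E| / (n(n-1))
TL      sum of edge lengths / (2 d n(n-1)/2)   (max 0.5)
RW      (n ln n) / mean cover time of a simple random walk; 0 if
        the graph is disconnected
EG      mean component of the dominant adjacency eigenvector found
        by power iteration from the degree sequence; 0 if the
        iteration does not converge
CC      number of connected components / n
CL      clique number omega(G) / n           (exact)
DN      domination number gamma(G) / n       (exact)
IN      independence number alpha(G) / n     (exact)
LC      mean local clustering coefficient
GC      global clustering (transitivity), 3 * triangles / triplets
======  ==========================================================

RW and EG can exceed 1 on very small graphs (e.g. RW on a single edge is
2 ln 2); no clamping is applied.  The NP-hard indices (CL, DN, IN) are
computed exactly — CL and IN by igraph's C branch-and-bound, DN by a bitmask
branch-and-bound over closed neighborhoods — never by a heuristic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import igraph as ig
import numpy as np

from .geomgraph import GeometricGraph, n_components

__all__ = [
    "IndexValue",
    "INDEX_NAMES",
    "total_degree",
    "total_edge_length",
    "connected_components_index",
    "clique_number_index",
    "domination_number_index",
    "independence_number_index",
    "local_clustering_index",
    "global_clustering_index",
    "random_walk_index",
    "eigenvector_centrality_index",
    "compute_all",
    "clique_number",
    "domination_number",
    "independence_number",
]

#: Canonical index order used throughout tables and reports.
INDEX_NAMES = ("TD", "TL", "RW", "EG", "CC", "CL", "DN", "IN", "LC", "GC")


@dataclass(frozen=True)
class IndexValue:
    index_name: str
    value: float
    d: float
    pattern_id: str = ""
    mc_error: float | None = None  # sampling SE, stochastic indices only


class DegenerateGraphError(ValueError):
    """Raised for graphs too small for the requested index."""


def _iv(name: str, value: float, g: GeometricGraph, mc_error: float | None = None) -> IndexValue:
    return IndexValue(name, float(value), g.d, g.source.pattern_id, mc_error)


# --------------------------------------------------------------------------
# Cheap combinatorial indices

def total_degree(g: GeometricGraph) -> IndexValue:
    """TD: sum of degrees over its maximum n(n-1), i.e. graph density."""
    if g.n < 2:
        raise DegenerateGraphError("TD requires n >= 2")
    return _iv("TD", 2 * g.edge_count / (g.n * (g.n - 1)), g)


def total_edge_length(g: GeometricGraph) -> IndexValue:
    """TL: sum of edge lengths over its ceiling 2 d * n(n-1)/2.

    The ceiling is attained by a complete graph with every pair at distance
    exactly d, so TL is in [0, 0.5] (the customary 0.5 ceiling of this
    normalization is kept as is).  The divisor is the fixed maximum edge
    count, not the graph's own |E|: dividing by |E| would make TL a mean
    edge length, whose across-pattern spread peaks at degenerate small d
    instead of tracking total wiring cost.
    """
    if g.n < 2:
        raise DegenerateGraphError("TL requires n >= 2")
    if g.d == 0:
        return _iv("TL", 0.0, g)
    return _iv("TL", g.edge_lengths.sum() / (g.d * g.n * (g.n - 1)), g)


def connected_components_index(g: GeometricGraph) -> IndexValue:
    """CC: number of connected components / n."""
    return _iv("CC", n_components(g) / g.n, g)


def _triangles_per_vertex(adj: np.ndarray) -> np.ndarray:
    a = adj.astype(np.float64)
    # t_v = number of edges among N(v) = triangles through v
    return ((a @ a) * a).sum(axis=1) / 2.0


def local_clustering_index(g: GeometricGraph) -> IndexValue:
    """LC: mean of the Watts-Strogatz local coefficient, 0 for deg < 2."""
    deg = g.degrees().astype(float)
    t = _triangles_per_vertex(g.adjacency)
    denom = deg * (deg - 1)
    lc = np.divide(2.0 * t, denom, out=np.zeros_like(t), where=denom > 0)
    return _iv("LC", lc.sum() / g.n, g)


def global_clustering_index(g: GeometricGraph) -> IndexValue:
    """GC: 3 * triangles / connected triplets; 0 when there are no triplets."""
    deg = g.degrees().astype(float)
    triplets = (deg * (deg - 1) / 2.0).sum()
    if triplets == 0:
        return _iv("GC", 0.0, g)
    triangles = _triangles_per_vertex(g.adjacency).sum() / 3.0
    return _iv("GC", 3.0 * triangles / triplets, g)


# --------------------------------------------------------------------------
# Exact NP-hard indices

def _to_igraph(g: GeometricGraph) -> ig.Graph:
    return ig.Graph(n=g.n, edges=[tuple(e) for e in g.edges])


def clique_number(g: GeometricGraph) -> int:
    """omega(G), exact (igraph branch-and-bound)."""
    return int(_to_igraph(g).clique_number())


def independence_number(g: GeometricGraph) -> int:
    """alpha(G), exact (clique number of the complement)."""
    return int(_to_igraph(g).independence_number())


def domination_number(g: GeometricGraph) -> int:
    """gamma(G) by exact branch-and-bound over closed neighborhoods.

    Vertices are encoded as bits; the problem is minimum set cover of the
    vertex set by closed neighborhoods N[v].  Solved per connected
    component.  Branching picks an uncovered vertex with the fewest
    dominators and tries each of its dominators, which preserves exactness;
    pruning uses a greedy upper bound and the bound
    ceil(#uncovered / max coverage).
    """
    n = g.n
    if n == 0:
        return 0
    adj = g.adjacency
    total = 0
    _, labels = _cc_labels(adj)
    for comp in np.unique(labels):
        verts = np.flatnonzero(labels == comp)
        total += _domination_component(adj[np.ix_(verts, verts)])
    return total


def _cc_labels(adj: np.ndarray) -> tuple[int, np.ndarray]:
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    ncomp, labels = connected_components(csr_matrix(adj), directed=False)
    return ncomp, labels


def _domination_component(adj: np.ndarray) -> int:
    n = adj.shape[0]
    if n == 1:
        return 1
    closed = [1 << v for v in range(n)]
    for v in range(n):
        for u in np.flatnonzero(adj[v]):
            closed[v] |= 1 << int(u)
    full = (1 << n) - 1

    # greedy upper bound
    covered, greedy = 0, 0
    while covered != full:
        best = max(range(n), key=lambda v: bin(closed[v] & ~covered).count("1"))
        covered |= closed[best]
        greedy += 1
    best_size = greedy

    order = sorted(range(n), key=lambda v: -bin(closed[v]).count("1"))

    def dfs(covered: int, k: int) -> None:
        nonlocal best_size
        if covered == full:
            best_size = min(best_size, k)
            return
        rem = full & ~covered
        maxcov = max(bin(closed[v] & rem).count("1") for v in range(n))
        if k + math.ceil(bin(rem).count("1") / maxcov) >= best_size:
            return
        # branch on an uncovered vertex with fewest dominators
        u_best, doms_best = -1, None
        for u in range(n):
            if rem >> u & 1:
                doms = [v for v in order if closed[v] >> u & 1]
                if doms_best is None or len(doms) < len(doms_best):
                    u_best, doms_best = u, doms
                    if len(doms) == 1:
                        break
        for v in sorted(doms_best, key=lambda v: -bin(closed[v] & rem).count("1")):
            dfs(covered | closed[v], k + 1)

    dfs(0, 0)
    return best_size


def clique_number_index(g: GeometricGraph) -> IndexValue:
    return _iv("CL", clique_number(g) / g.n, g)


def domination_number_index(g: GeometricGraph) -> IndexValue:
    return _iv("DN", domination_number(g) / g.n, g)


def independence_number_index(g: GeometricGraph) -> IndexValue:
    return _iv("IN", independence_number(g) / g.n, g)


# --------------------------------------------------------------------------
# Stochastic / iterative indices

def _padded_neighbors(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    deg = adj.sum(axis=1).astype(np.int64)
    maxdeg = int(deg.max()) if deg.size else 0
    nbrs = np.zeros((adj.shape[0], max(maxdeg, 1)), dtype=np.int64)
    for v in range(adj.shape[0]):
        nv = np.flatnonzero(adj[v])
        nbrs[v, : nv.size] = nv
    return nbrs, deg


def cover_times(g: GeometricGraph, walks: int, rng: np.random.Generator) -> np.ndarray:
    """Steps for simple random walks to visit every vertex at least once.

    Each walk starts at a uniformly random vertex (which counts as visited)
    and moves to a uniformly random neighbor per step; a step is counted on
    every edge traversal.  The graph must be connected.  Walks are simulated
    in parallel across the batch.
    """
    n = g.n
    if n == 1:
        return np.zeros(walks, dtype=np.int64)
    nbrs, deg = _padded_neighbors(g.adjacency)
    cur = rng.integers(0, n, walks)
    visited = np.zeros((walks, n), dtype=bool)
    visited[np.arange(walks), cur] = True
    count = np.ones(walks, dtype=np.int64)
    steps = np.zeros(walks, dtype=np.int64)
    active = np.flatnonzero(count < n)
    while active.size:
        c = cur[active]
        nxt = nbrs[c, (rng.random(active.size) * deg[c]).astype(np.int64)]
        cur[active] = nxt
        newly = ~visited[active, nxt]
        visited[active, nxt] = True
        count[active] += newly
        steps[active] += 1
        active = active[count[active] < n]
    return steps


def random_walk_index(g: GeometricGraph, walks: int = 1000, seed: int | np.random.Generator = 0) -> IndexValue:
    """RW: (n ln n) / mean cover time; 0 for disconnected graphs.

    The normalizer n ln n is the asymptotic lower bound for cover times;
    values above 1 are possible for very small n and are not clamped.
    ``mc_error`` is the propagated standard error of the mean cover time.
    """
    if walks < 1:
        raise ValueError("walks must be >= 1")
    if n_components(g) != 1:
        return _iv("RW", 0.0, g, mc_error=0.0)
    if g.n == 1:
        return _iv("RW", 0.0, g, mc_error=0.0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = cover_times(g, walks, rng)
    tbar = t.mean()
    se_t = t.std(ddof=1) / math.sqrt(walks) if walks > 1 else 0.0
    norm = g.n * math.log(g.n)
    value = norm / tbar
    return _iv("RW", value, g, mc_error=norm * se_t / tbar**2)


def eigenvector_centrality_index(
    g: GeometricGraph, max_iters: int = 1000, tol: float = 1e-6,
    connected_only: bool = True,
) -> IndexValue:
    """EG: mean component of the dominant adjacency eigenvector.

    Power iteration starts from the degree sequence and renormalizes to unit
    Euclidean length after every multiplication; convergence is successive
    iterates within ``tol`` in max-norm.  If the iteration does not converge
    within ``max_iters`` (edgeless graphs, or bipartite graphs where the
    +/-lambda pair makes iterates oscillate), the index is 0 by convention.

    By default EG is 0 for disconnected graphs, like RW: on a disconnected
    graph the dominant eigenvector is supported on one component only, so
    the mean component measures component-size lottery rather than
    centrality structure, and its across-pattern spread peaks at a
    degenerate small d.  ``connected_only=False`` runs the iteration on the
    whole graph instead (it gravitates to the dominant component's
    eigenvector).
    """
    if max_iters < 1 or tol <= 0:
        raise ValueError("max_iters >= 1 and tol > 0 required")
    if connected_only and n_components(g) != 1:
        return _iv("EG", 0.0, g)
    a = g.adjacency.astype(float)
    x = g.degrees().astype(float)
    nrm = np.linalg.norm(x)
    if nrm == 0:  # edgeless: zero start can never converge to an eigenpair
        return _iv("EG", 0.0, g)
    x /= nrm
    for _ in range(max_iters):
        y = a @ x
        nrm = np.linalg.norm(y)
        if nrm == 0:
            return _iv("EG", 0.0, g)
        y /= nrm
        if np.max(np.abs(y - x)) < tol:
            return _iv("EG", float(y.mean()), g)
        x = y
    return _iv("EG", 0.0, g)


# --------------------------------------------------------------------------

_DISPATCH = {
    "TD": total_degree,
    "TL": total_edge_length,
    "CC": connected_components_index,
    "CL": clique_number_index,
    "DN": domination_number_index,
    "IN": independence_number_index,
    "LC": local_clustering_index,
    "GC": global_clustering_index,
}


def compute_all(
    g: GeometricGraph,
    indices: tuple[str, ...] = INDEX_NAMES,
    walks: int = 1000,
    max_iters: int = 1000,
    tol: float = 1e-6,
    seed: int | np.random.Generator = 0,
) -> list[IndexValue]:
    """Evaluate the requested indices on one graph with shared settings.

    Per-index failures are captured as NaN-valued entries rather than
    aborting the batch.
    """
    out: list[IndexValue] = []
    for name in indices:
        try:
            if name == "RW":
                out.append(random_walk_index(g, walks=walks, seed=seed))
            elif name == "EG":
                out.append(eigenvector_centrality_index(g, max_iters=max_iters, tol=tol))
            elif name in _DISPATCH:
                out.append(_DISPATCH[name](g))
            else:
                raise KeyError(f"unknown index {name!r}")
        except KeyError:
            raise
        except Exception:
            out.append(_iv(name, float("nan"), g))
    return out
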