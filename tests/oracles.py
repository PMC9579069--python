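"""Independent brute-force oracles used by the test suite.

Everything here enumerates exhaustively over vertex subsets (bitmask
encoded), so it is exact for small n and entirely independent of the
package's solvers.
"""

from __future__ import annotations

import numpy as np


def adjacency_bitmasks(adj: np.ndarray) -> list[int]:
    n = adj.shape[0]
    return [int(sum(1 << j for j in np.flatnonzero(adj[i]))) for i in range(n)]


def brute_clique_number(adj: np.ndarray) -> int:
    n = adj.shape[0]
    nb = adjacency_bitmasks(adj)
    best = 0
    for s in range(1, 1 << n):
        members = [v for v in range(n) if s >> v & 1]
        if len(members) <= best:
            continue
        if all(nb[v] & s == s & ~(1 << v) for v in members):
            best = len(members)
    return best


def brute_independence_number(adj: np.ndarray) -> int:
    n = adj.shape[0]
    nb = adjacency_bitmasks(adj)
    best = 0
    for s in range(1, 1 << n):
        members = [v for v in range(n) if s >> v & 1]
        if len(members) <= best:
            continue
        if all(nb[v] & s == 0 for v in members):
            best = len(members)
    return best


def brute_domination_number(adj: np.ndarray) -> int:
    n = adj.shape[0]
    nb = adjacency_bitmasks(adj)
    closed = [nb[v] | (1 << v) for v in range(n)]
    full = (1 << n) - 1
    best = n
    for s in range(1, 1 << n):
        cover = 0
        for v in range(n):
            if s >> v & 1:
                cover |= closed[v]
        if cover == full:
            k = bin(s).count("1")
            if k < best:
                best = k
    return best


def brute_components(adj: np.ndarray) -> int:
    """Component count by transitive closure."""
    n = adj.shape[0]
    reach = adj.astype(bool) | np.eye(n, dtype=bool)
    for _ in range(n):
        reach = reach | (reach @ reach)
    return len({tuple(row) for row in reach})


def random_graph(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    """Symmetric Erdos-Renyi adjacency matrix."""
    a = rng.random((n, n)) < p
    a = np.triu(a, 1)
    return a | a.T


def two_disk_union_area(s: float, r: float) -> float:
    """Closed-form union area of two radius-r disks at center distance s."""
    if s >= 2 * r:
        return 2 * np.pi * r**2
    lens = 2 * r**2 * np.arccos(s / (2 * r)) - (s / 2) * np.sqrt(4 * r**2 - s**2)
    return 2 * np.pi * r**2 - lens
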