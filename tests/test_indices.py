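"""The ten graph indices: closed-form examples, exact-solver oracles,
stochastic-index laws, and order/monotonicity properties."""

import math

import numpy as np
import pytest

import numgraph as ng
from numgraph import indices as gi
from numgraph.geomgraph import GeometricGraph

from .conftest import R, SEED
from .oracles import (
    brute_clique_number,
    brute_domination_number,
    brute_independence_number,
    random_graph,
)


def geo(points, d):
    return ng.build_graph(
        ng.PointConfiguration(points=np.asarray(points, float), R=1000.0), d
    )


def from_adjacency(adj) -> GeometricGraph:
    """Wrap an abstract adjacency matrix (non-geometric test graphs)."""
    adj = np.asarray(adj, bool)
    src = ng.PointConfiguration(points=np.zeros((adj.shape[0], 2)), R=1.0)
    return GeometricGraph(adjacency=adj, d=1.0, source=src)


def _polygon(n):
    ang = 2 * np.pi * np.arange(n) / n
    pts = np.column_stack((np.cos(ang), np.sin(ang)))
    side = np.hypot(*(pts[0] - pts[1]))
    return pts, side


@pytest.fixture()
def k4_minus_edge():
    # rhombus: all pairs within d except the two apexes
    return geo([(0, 0), (1, 0), (0.5, 0.7), (0.5, -0.7)], d=1.0)


# --------------------------------------------------------------------------
# closed-form examples


def test_total_degree_examples():
    cfg = ng.generate_pattern(40, R=R, seed=SEED)
    assert gi.total_degree(ng.build_graph(cfg, 2 * R)).value == 1.0
    assert gi.total_degree(ng.build_graph(cfg, 0)).value == 0.0
    path3 = geo([(0, 0), (1, 0), (2, 0)], d=1)
    assert gi.total_degree(path3).value == pytest.approx(2 / 3)
    with pytest.raises(gi.DegenerateGraphError):
        gi.total_degree(geo([(0, 0)], d=1))


def test_total_edge_length_examples():
    # right triangle with sides 3, 4, 5 at d = 5: complete, so the ceiling
    # divisor equals 2 d |E| and TL = 12 / (2*5*3)
    tri = geo([(0, 0), (3, 0), (0, 4)], d=5)
    assert gi.total_edge_length(tri).value == pytest.approx(0.4)
    pair = geo([(0, 0), (7, 0)], d=7)
    assert gi.total_edge_length(pair).value == pytest.approx(0.5)  # ceiling
    edgeless = geo([(0, 0), (50, 0)], d=1)
    assert gi.total_edge_length(edgeless).value == 0.0


def test_connected_components_examples():
    cfg = ng.generate_pattern(20, R=R, seed=SEED)
    assert gi.connected_components_index(ng.build_graph(cfg, 0)).value == 1.0
    assert gi.connected_components_index(ng.build_graph(cfg, 2 * R)).value == 1 / 20
    # ten well-separated 4-point clusters -> ten components, 40 vertices
    clusters = [
        (200 * k + dx, dy)
        for k in range(10)
        for dx, dy in ((0, 0), (5, 0), (2.5, 8), (2.5, -8))
    ]
    g = geo(clusters, d=10)
    assert gi.connected_components_index(g).value == pytest.approx(10 / 40)


def test_clique_examples():
    cfg = ng.generate_pattern(12, R=R, seed=SEED)
    assert gi.clique_number_index(ng.build_graph(cfg, 2 * R)).value == 1.0
    assert gi.clique_number_index(ng.build_graph(cfg, 0)).value == pytest.approx(1 / 12)


def test_domination_examples():
    cfg = ng.generate_pattern(8, R=R, seed=SEED)
    assert gi.domination_number_index(ng.build_graph(cfg, 0)).value == 1.0
    star = geo([(0, 0)] + list(zip(np.cos(2 * np.pi * np.arange(5) / 5), np.sin(2 * np.pi * np.arange(5) / 5))), d=1.0)
    assert gi.domination_number_index(star).value == pytest.approx(1 / 6)
    pts, side = _polygon(6)
    c6 = geo(pts, d=side + 1e-9)
    assert gi.domination_number_index(c6).value == pytest.approx(2 / 6)


def test_independence_examples():
    cfg = ng.generate_pattern(9, R=R, seed=SEED)
    assert gi.independence_number_index(ng.build_graph(cfg, 0)).value == 1.0
    assert gi.independence_number_index(ng.build_graph(cfg, 2 * R)).value == pytest.approx(1 / 9)
    pts, side = _polygon(5)
    c5 = geo(pts, d=side + 1e-9)
    assert gi.independence_number_index(c5).value == pytest.approx(2 / 5)


def test_local_clustering_examples(k4_minus_edge):
    tri = geo([(0, 0), (1, 0), (0.5, 0.8)], d=1.0)
    assert gi.local_clustering_index(tri).value == 1.0
    path3 = geo([(0, 0), (1, 0), (2, 0)], d=1)
    assert gi.local_clustering_index(path3).value == 0.0
    assert gi.local_clustering_index(k4_minus_edge).value == pytest.approx(5 / 6)


def test_global_clustering_examples(k4_minus_edge):
    tri = geo([(0, 0), (1, 0), (0.5, 0.8)], d=1.0)
    assert gi.global_clustering_index(tri).value == 1.0
    star = geo([(0, 0)] + list(zip(np.cos(2 * np.pi * np.arange(5) / 5), np.sin(2 * np.pi * np.arange(5) / 5))), d=1.0)
    assert gi.global_clustering_index(star).value == 0.0
    assert gi.global_clustering_index(k4_minus_edge).value == pytest.approx(0.75)


# --------------------------------------------------------------------------
# exact solvers vs exhaustive enumeration


def test_exact_solvers_match_brute_force(rng):
    for _ in range(200):
        n = int(rng.integers(4, 13))
        adj = random_graph(rng, n, float(rng.uniform(0.1, 0.9)))
        g = from_adjacency(adj)
        assert gi.clique_number(g) == brute_clique_number(adj)
        assert gi.independence_number(g) == brute_independence_number(adj)
        assert gi.domination_number(g) == brute_domination_number(adj)


def test_order_relations_on_geometric_graphs(rng):
    # DN <= IN (maximal independent sets dominate) and
    # CC <= IN (one vertex per component is independent)
    for seed in range(15):
        cfg = ng.generate_pattern(25, R=R, seed=seed)
        for d in (20, 50, 90, 150):
            g = ng.build_graph(cfg, d)
            dn = gi.domination_number(g)
            indep = gi.independence_number(g)
            from numgraph.geomgraph import n_components

            assert dn <= indep
            assert n_components(g) <= indep


def test_monotonicity_in_d():
    cfg = ng.generate_pattern(24, R=R, seed=SEED)
    grid = [15, 40, 80, 140, 220, 320]
    td, cl, cc, dn, indep = [], [], [], [], []
    for d in grid:
        g = ng.build_graph(cfg, d)
        td.append(gi.total_degree(g).value)
        cl.append(gi.clique_number_index(g).value)
        cc.append(gi.connected_components_index(g).value)
        dn.append(gi.domination_number_index(g).value)
        indep.append(gi.independence_number_index(g).value)
    assert all(a <= b for a, b in zip(td, td[1:]))
    assert all(a <= b for a, b in zip(cl, cl[1:]))
    assert all(a >= b for a, b in zip(cc, cc[1:]))
    assert all(a >= b for a, b in zip(dn, dn[1:]))
    assert all(a >= b for a, b in zip(indep, indep[1:]))


# --------------------------------------------------------------------------
# random walk cover time


def test_rw_zero_on_disconnected():
    g = geo([(0, 0), (1, 0), (50, 0), (51, 0)], d=2)
    assert gi.random_walk_index(g, walks=10, seed=SEED).value == 0.0


def test_rw_single_edge_exact():
    g = geo([(0, 0), (1, 0)], d=1)
    iv = gi.random_walk_index(g, walks=50, seed=SEED)
    # cover needs exactly one step from either start
    assert iv.value == pytest.approx(2 * math.log(2))
    assert iv.mc_error == 0.0


def test_rw_complete_graph_coupon_collector(rng):
    # cover time of K_n is the (n-1)-coupon collector: E = (n-1) H_{n-1}
    from numgraph.indices import cover_times

    n = 20
    cfg = ng.generate_pattern(n, R=R, seed=SEED)
    g = ng.build_graph(cfg, 2 * R)
    t = cover_times(g, 2000, rng)
    expected = (n - 1) * sum(1 / k for k in range(1, n))
    se = t.std(ddof=1) / math.sqrt(len(t))
    assert abs(t.mean() - expected) < 3 * se


def test_rw_reproducible_given_seed():
    cfg = ng.generate_pattern(30, R=R, seed=SEED)
    g = ng.build_graph(cfg, 100)
    a = gi.random_walk_index(g, walks=200, seed=42)
    b = gi.random_walk_index(g, walks=200, seed=42)
    assert a.value == b.value and a.mc_error == b.mc_error


# --------------------------------------------------------------------------
# eigenvector centrality


def test_eg_single_edge_and_complete():
    pair = geo([(0, 0), (1, 0)], d=1)
    assert gi.eigenvector_centrality_index(pair).value == pytest.approx(1 / math.sqrt(2))
    k4 = geo([(0, 0), (1, 0), (0.5, 0.7), (0.5, -0.7)], d=1.5)
    assert gi.eigenvector_centrality_index(k4).value == pytest.approx(0.5)


def test_eg_vertex_transitive_returns_inverse_sqrt_n():
    pts, side = _polygon(5)
    c5 = geo(pts, d=side + 1e-9)
    assert gi.eigenvector_centrality_index(c5).value == pytest.approx(1 / math.sqrt(5))


def test_eg_edgeless_and_disconnected_zero():
    edgeless = geo([(0, 0), (50, 0), (100, 0)], d=1)
    assert gi.eigenvector_centrality_index(edgeless).value == 0.0
    two_pairs = geo([(0, 0), (1, 0), (50, 0), (51.5, 0)], d=2)
    assert gi.eigenvector_centrality_index(two_pairs).value == 0.0
    # whole-graph mode runs anyway and lands on the dominant component
    v = gi.eigenvector_centrality_index(two_pairs, connected_only=False).value
    assert v > 0


def test_eg_bipartite_oscillation_yields_zero():
    # P3's dominant/secondary eigenvalues are +/-sqrt(2); power iteration
    # from the degree sequence oscillates, so the convention value is 0
    path3 = geo([(0, 0), (1, 0), (2, 0)], d=1)
    assert gi.eigenvector_centrality_index(path3).value == 0.0


# --------------------------------------------------------------------------
# batch evaluation


def test_compute_all_complete_and_edgeless_limits():
    cfg40 = ng.generate_pattern(40, R=R, seed=SEED)
    vals = {iv.index_name: iv.value for iv in gi.compute_all(ng.build_graph(cfg40, 2 * R), walks=50)}
    assert vals["TD"] == 1.0
    assert vals["CC"] == pytest.approx(1 / 40)
    assert vals["CL"] == 1.0
    assert vals["DN"] == pytest.approx(1 / 40)
    assert vals["IN"] == pytest.approx(1 / 40)
    assert vals["LC"] == 1.0
    assert vals["GC"] == 1.0

    cfg22 = ng.generate_pattern(22, R=R, seed=SEED)
    vals = {iv.index_name: iv.value for iv in gi.compute_all(ng.build_graph(cfg22, 0), walks=10)}
    assert vals == {
        "TD": 0.0, "TL": 0.0, "RW": 0.0, "EG": 0.0, "CC": 1.0,
        "CL": pytest.approx(1 / 22), "DN": 1.0, "IN": 1.0, "LC": 0.0, "GC": 0.0,
    }


def test_compute_all_consistent_with_individual_calls():
    cfg = ng.generate_pattern(22, R=R, seed=SEED)
    g = ng.build_graph(cfg, R / 2)
    batch = {iv.index_name: iv.value for iv in gi.compute_all(g, walks=100, seed=SEED)}
    assert batch["RW"] == gi.random_walk_index(g, walks=100, seed=SEED).value
    assert batch["EG"] == gi.eigenvector_centrality_index(g).value
    assert batch["DN"] == gi.domination_number_index(g).value
    assert batch["TL"] == gi.total_edge_length(g).value
    for name, value in batch.items():
        if name in ("RW", "EG"):
            assert value >= 0
        else:
            assert 0 <= value <= 1
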