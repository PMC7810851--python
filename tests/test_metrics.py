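"""Network index tests: wiring cost, MST/Delaunay bounds, efficiency,
betweenness and fault tolerance, checked against exhaustive oracles."""

import itertools
from math import sqrt

import networkx as nx
import numpy as np
import pytest
from conftest import (
    betweenness_oracle,
    floyd_warshall_oracle,
    ft_exhaustive_oracle,
    geometric_graph,
    mst_weight_oracle,
    simple_square_graph,
)

from veinnet.metrics import (
    all_pairs_paths,
    delaunay_graph,
    drag_efficiency,
    edge_betweenness,
    fault_tolerance_decay,
    fault_tolerance_random,
    fault_tolerance_raw,
    length_efficiency,
    normalized_network_length,
    reference_graphs,
    wiring_cost_and_tortuosity,
)


def straight_chain(lengths, widths=None):
    """Collinear chain with straight edges (length == euclid)."""
    g = nx.Graph(px_per_mm=10.0)
    x = 0.0
    g.add_node(0, x_mm=0.0, y_mm=0.0, px=(0.0, 0.0))
    for i, L in enumerate(lengths, start=1):
        x += L
        g.add_node(i, x_mm=x, y_mm=0.0, px=(0.0, x * 10))
        w = 0.5 if widths is None else widths[i - 1]
        g.add_edge(i - 1, i, length_mm=L, euclid_mm=L, width_mm=w, drag=L / w**4)
    return g


class TestWiringCost:
    def test_cost_is_edge_sum(self):
        g = straight_chain([1.0, 2.0, 3.0])
        cl, ce, tort = wiring_cost_and_tortuosity(g)
        assert cl == pytest.approx(6.0)
        assert tort == pytest.approx(1.0)

    def test_semicircular_edge_tortuosity(self):
        g = nx.Graph(px_per_mm=10.0)
        r = 2.0
        g.add_node(0, x_mm=0.0, y_mm=0.0, px=(0.0, 0.0))
        g.add_node(1, x_mm=2 * r, y_mm=0.0, px=(0.0, 2 * r * 10))
        g.add_edge(0, 1, length_mm=np.pi * r, euclid_mm=2 * r, width_mm=0.5,
                   drag=np.pi * r / 0.5**4)
        _, _, tort = wiring_cost_and_tortuosity(g)
        assert tort == pytest.approx(np.pi / 2)


class TestReferenceGraphs:
    def test_mst_drops_heaviest_cycle_edge(self):
        g = nx.Graph(px_per_mm=10.0)
        coords = [(0, 0), (1, 0), (1, 1), (0, 1)]
        for i, (x, y) in enumerate(coords):
            g.add_node(i, x_mm=float(x), y_mm=float(y), px=(y * 10.0, x * 10.0))
        lengths = {(0, 1): 1.0, (1, 2): 1.0, (2, 3): 1.0, (3, 0): 2.0}
        for (u, v), L in lengths.items():
            g.add_edge(u, v, length_mm=L, euclid_mm=1.0, width_mm=0.5, drag=L / 0.5**4)
        mst, _ = reference_graphs(g, weight="length_mm")
        # brute force: enumerate all spanning trees
        best = mst_weight_oracle(g, "length_mm")
        got = sum(d["length_mm"] for _, _, d in mst.edges(data=True))
        assert got == pytest.approx(best) == pytest.approx(3.0)
        assert not mst.has_edge(3, 0)

    def test_drag_weighted_mst_keeps_wider_parallel_route(self):
        # two geometrically identical routes, one wider: the drag MST
        # must strictly keep the wide one
        g = nx.Graph(px_per_mm=10.0)
        pts = {0: (0, 0), 1: (1, 1), 2: (1, -1), 3: (2, 0)}
        for n, (x, y) in pts.items():
            g.add_node(n, x_mm=float(x), y_mm=float(y), px=(y * 10.0, x * 10.0))
        e = sqrt(2)
        for u, v, w in [(0, 1, 0.5), (1, 3, 0.5), (0, 2, 1.0), (2, 3, 1.0)]:
            g.add_edge(u, v, length_mm=e, euclid_mm=e, width_mm=w, drag=e / w**4)
        mst, _ = reference_graphs(g, weight="drag")
        assert mst.has_edge(0, 2) and mst.has_edge(2, 3)
        # of the two thin-route edges exactly one survives (tree needs 3)
        assert mst.number_of_edges() == 3

    def test_unit_square_delaunay_has_five_edges(self, simple_square_graph):
        dt = delaunay_graph(simple_square_graph)
        assert dt.number_of_edges() == 5  # 4 sides + 1 diagonal

    def test_collinear_nodes_fall_back_to_path(self):
        g = straight_chain([1.0, 1.0, 1.0])
        dt = delaunay_graph(g)
        assert dt.number_of_edges() == 3
        assert nx.is_connected(dt)


class TestNNL:
    def test_mst_maps_to_zero(self, simple_square_graph):
        mst, _ = reference_graphs(simple_square_graph, weight="length_mm")
        mst.graph.update(simple_square_graph.graph)
        assert normalized_network_length(mst) == pytest.approx(0.0)

    def test_delaunay_edge_set_maps_to_one(self, simple_square_graph):
        dt = delaunay_graph(simple_square_graph)
        for _, _, d in dt.edges(data=True):
            d.setdefault("width_mm", 0.5)
            d.setdefault("drag", d["length_mm"] / 0.5**4)
        assert normalized_network_length(dt) == pytest.approx(1.0)

    def test_unit_square_cycle_closed_form(self, simple_square_graph):
        # cost 4, MST 3, DT 4 + sqrt(2): NNL = 1 / (1 + sqrt(2))
        got = normalized_network_length(simple_square_graph)
        assert got == pytest.approx(1.0 / (1.0 + sqrt(2))) == pytest.approx(0.414, abs=5e-4)


class TestAllPairs:
    def test_collinear_chain_trivial(self):
        g = straight_chain([1.0, 1.0])
        pm = all_pairs_paths(g)
        i, j = pm.nodes.index(0), pm.nodes.index(2)
        assert pm.l[i, j] == pytest.approx(2.0)
        assert pm.e[i, j] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_floyd_warshall_oracle(self, seed):
        g = geometric_graph(seed, n=12)
        pm = all_pairs_paths(g)
        for weight, mat in (("length_mm", pm.l), ("drag", pm.d)):
            oracle = floyd_warshall_oracle(g, weight)
            for a, u in enumerate(pm.nodes):
                for b, v in enumerate(pm.nodes):
                    assert mat[a, b] == pytest.approx(oracle[(u, v)])

    def test_single_edge_reference_drag(self):
        g = straight_chain([1.0], widths=[0.5])
        pm = all_pairs_paths(g)
        assert pm.d[0, 1] == pytest.approx(16.0)
        assert pm.c[0, 1] == pytest.approx(16.0)


class TestEfficiency:
    def test_straight_tree_has_unit_le(self):
        g = straight_chain([1.0, 2.0, 0.5])
        le, mean, cov = length_efficiency(all_pairs_paths(g))
        assert le == pytest.approx(1.0)
        assert cov == pytest.approx(0.0)

    def test_two_node_le_forced(self):
        g = nx.Graph(px_per_mm=10.0)
        g.add_node(0, x_mm=0.0, y_mm=0.0, px=(0.0, 0.0))
        g.add_node(1, x_mm=1.0, y_mm=0.0, px=(0.0, 10.0))
        g.add_edge(0, 1, length_mm=2.0, euclid_mm=1.0, width_mm=0.5, drag=32.0)
        le, _, _ = length_efficiency(all_pairs_paths(g))
        assert le == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_le_and_ratios_bounded_by_one(self, seed):
        pm = all_pairs_paths(geometric_graph(seed, n=10))
        le, mean, _ = length_efficiency(pm)
        assert 0 < le <= 1.0 + 1e-9
        iu = np.triu_indices(len(pm.nodes), k=1)
        assert np.all(pm.e[iu] / pm.l[iu] <= 1.0 + 1e-9)

    def test_drag_efficiency_reference_width(self):
        assert drag_efficiency(all_pairs_paths(straight_chain([1.0], [0.5])))[0] == pytest.approx(1.0)
        assert drag_efficiency(all_pairs_paths(straight_chain([1.0], [1.0])))[0] == pytest.approx(0.0625)

    @pytest.mark.parametrize("seed", range(5))
    def test_widening_an_edge_never_increases_drag_ratio(self, seed):
        g = geometric_graph(seed, n=10)
        pm = all_pairs_paths(g)
        rng = np.random.default_rng(seed)
        edges = list(g.edges())
        u, v = edges[rng.integers(len(edges))]
        g2 = g.copy()
        g2[u][v]["width_mm"] *= 2.0
        g2[u][v]["drag"] = g2[u][v]["length_mm"] / g2[u][v]["width_mm"] ** 4
        pm2 = all_pairs_paths(g2)
        assert np.all(pm2.d <= pm.d + 1e-9)


class TestBetweenness:
    def test_star_spokes_serve_half_of_pairs(self):
        g = nx.star_graph(3)
        for u, v in g.edges():
            g[u][v].update(length_mm=1.0, drag=16.0)
        for n in g.nodes:
            g.nodes[n].update(x_mm=float(n), y_mm=0.0, px=(0.0, float(n)))
        pct, mu = edge_betweenness(g, weight="length_mm")
        assert all(v == pytest.approx(50.0) for v in pct.values())
        assert mu == pytest.approx(50.0)

    def test_path_edge_fraction(self):
        g = straight_chain([1.0, 1.0])
        pct, _ = edge_betweenness(g, weight="length_mm")
        assert sorted(pct.values()) == pytest.approx([200 / 3, 200 / 3])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        g = geometric_graph(seed, n=7)
        for weight in ("length_mm", "drag"):
            got, mu = edge_betweenness(g, weight=weight)
            oracle = betweenness_oracle(g, weight)
            for e, v in got.items():
                assert v == pytest.approx(oracle[frozenset(e)], abs=1e-6)
            assert mu == pytest.approx(np.mean(list(oracle.values())))


class TestFaultTolerance:
    def test_single_edge_two_nodes_ft_is_one(self):
        g = straight_chain([1.0])
        ft = fault_tolerance_raw(g, percents=(50,), reps=5,
                                 rng=np.random.default_rng(0))
        assert ft[50] == pytest.approx(1.0)

    def test_k4_matches_exhaustive_average(self):
        g = nx.complete_graph(4)
        for u, v in g.edges():
            g[u][v].update(length_mm=1.0, euclid_mm=1.0, width_mm=0.5, drag=16.0)
        for n in g.nodes:
            g.nodes[n].update(x_mm=float(n % 2), y_mm=float(n // 2),
                              px=(float(n // 2), float(n % 2)))
        exact = ft_exhaustive_oracle(g, 75.0)
        reps = 400
        ft = fault_tolerance_raw(g, percents=(75,), reps=reps,
                                 rng=np.random.default_rng(1))
        # Monte-Carlo sigma of the mean, bounded by the per-rep spread
        sigma = 0.5 / sqrt(reps)
        assert abs(ft[75] - exact) <= 3 * sigma

    @pytest.mark.parametrize("seed", range(4))
    def test_ft_monotone_in_connectivity_requirement(self, seed):
        g = geometric_graph(seed, n=10)
        ft = fault_tolerance_raw(g, percents=(25, 50, 75), reps=10,
                                 rng=np.random.default_rng(seed))
        assert ft[25] >= ft[50] >= ft[75]

    def test_normalized_ft_bounds(self):
        g = geometric_graph(3, n=12)
        ft_raw, ft_norm = fault_tolerance_random(g, reps=20, rng_seed=3)
        for p in (25, 50, 75):
            assert 0.0 <= ft_norm[p] <= 1.0

    def test_mst_normalizes_to_zero_and_dt_to_one(self):
        g = geometric_graph(2, n=12)
        mst, dt = reference_graphs(g, weight="length_mm")
        mst.graph.update(g.graph)
        for _, _, d in dt.edges(data=True):
            d.setdefault("width_mm", 0.5)
            d.setdefault("drag", d["length_mm"] / 0.5**4)
        _, norm_mst = fault_tolerance_random(mst, reps=30, rng_seed=5)
        _, norm_dt = fault_tolerance_random(dt, reps=30, rng_seed=5)
        for p in (50, 75):  # p=25 can be degenerate on small graphs
            assert norm_mst[p] == pytest.approx(0.0, abs=1e-9)
            assert norm_dt[p] == pytest.approx(1.0, abs=1e-9)


class TestDecayCurves:
    def test_no_removal_keeps_everything(self, simple_square_graph):
        curve = fault_tolerance_decay(simple_square_graph, order="worst")
        assert curve[-1] <= curve[0]
        assert curve.min() >= 0

    @pytest.mark.parametrize("seed", range(4))
    def test_worst_case_below_best_case_on_vein_graphs(self, seed):
        # the dominance property is an empirical feature of loopy vein
        # networks (small arbitrary graphs can violate it at high k)
        from veinnet.synthetic import generate_vein_graph

        g = generate_vein_graph(seed=seed)
        worst = fault_tolerance_decay(g, order="worst")
        best = fault_tolerance_decay(g, order="best")
        assert np.all(worst <= best + 1e-9)

    def test_barbell_bridge_removed_first_in_worst_order(self):
        # two triangles joined by one bridge: highest drag betweenness
        g = nx.Graph(px_per_mm=10.0)
        coords = {0: (0, 0), 1: (1, 0), 2: (0.5, 1), 3: (3, 0), 4: (4, 0), 5: (3.5, 1)}
        for n, (x, y) in coords.items():
            g.add_node(n, x_mm=float(x), y_mm=float(y), px=(y * 10.0, x * 10.0))
        tri = [(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3), (1, 3)]
        for u, v in tri:
            e = sqrt((coords[u][0] - coords[v][0]) ** 2 + (coords[u][1] - coords[v][1]) ** 2)
            g.add_edge(u, v, length_mm=e, euclid_mm=e, width_mm=0.5, drag=e / 0.5**4)
        worst = fault_tolerance_decay(g, order="worst")
        # removing ceil(1% * 7) = 1 edge: the bridge -> 50% connected
        assert worst[0] == pytest.approx(50.0)
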