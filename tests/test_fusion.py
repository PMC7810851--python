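"""Fusion detection, fusion-region geometry, connecting-vein counting
and inter-cell paths."""

from math import sqrt

import networkx as nx
import numpy as np
import pytest
from conftest import edge_disjoint_paths_oracle, geometric_graph

from veinnet.fusion import (
    NoFusionError,
    build_fusion_region,
    connecting_veins,
    detect_fusion_time,
    intercell_paths,
    source_nodes,
)


def two_discs(shape=(120, 200), r=20, c1=(60, 50), c2=(60, 150)):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    a = (rr - c1[0]) ** 2 + (cc - c1[1]) ** 2 <= r**2
    b = (rr - c2[0]) ** 2 + (cc - c2[1]) ** 2 <= r**2
    return a | b


class TestDetectFusionTime:
    def masks_with_bridge_at(self, t_bridge, n=12):
        base = two_discs()
        masks = []
        for t in range(n):
            m = base.copy()
            if t >= t_bridge:
                m[57:63, 50:150] = True
            masks.append(m)
        return masks

    def test_forward_scan_finds_merge_frame(self):
        assert detect_fusion_time(self.masks_with_bridge_at(7)) == 7

    def test_guess_refines_to_earliest(self):
        masks = self.masks_with_bridge_at(7)
        assert detect_fusion_time(masks, guess=11) == 7
        assert detect_fusion_time(masks, guess=2) == 7

    def test_never_fusing_raises(self):
        with pytest.raises(NoFusionError):
            detect_fusion_time(self.masks_with_bridge_at(99))


class TestBuildFusionRegion:
    def test_bridge_blob_becomes_connecting_set(self):
        bf = two_discs()
        af = bf.copy()
        bridge = np.zeros_like(bf)
        bridge[57:63, 68:133] = True
        af |= bridge
        region = build_fusion_region(bf, af, px_per_mm=2.0)
        new_growth = bridge & ~bf
        assert (region.connecting_set & new_growth).sum() == new_growth.sum()
        assert region.FR[region.connecting_set].all()
        # FR covers bridge + 5 mm slime collar + 2 mm offset
        assert region.FR.sum() > region.connecting_set.sum()

    def test_only_bridging_region_selected(self):
        bf = two_discs()
        af = bf.copy()
        af[57:63, 68:133] = True     # bridging growth
        af[10:18, 10:30] = True      # unrelated growth blob 1
        af[100:108, 160:180] = True  # unrelated growth blob 2
        region = build_fusion_region(bf, af, px_per_mm=2.0)
        assert not region.connecting_set[10:18, 10:30].any()
        assert not region.connecting_set[100:108, 160:180].any()
        assert region.connecting_set[58, 100]

    def test_no_new_growth_raises(self):
        bf = two_discs()
        with pytest.raises(ValueError):
            build_fusion_region(bf, bf.copy(), px_per_mm=2.0)

    def test_growth_that_never_connects_raises(self):
        bf = two_discs()
        af = bf.copy()
        af[10:18, 10:30] = True
        with pytest.raises(NoFusionError):
            build_fusion_region(bf, af, px_per_mm=2.0)


def corridor_graph(n_corridors=3, boost_safe=True):
    """Two hubs joined by edge-disjoint corridors through mid points.

    With ``boost_safe`` the mid-gap edges lie > 25 mm from both hubs so
    unit capacities govern the count.
    """
    g = nx.Graph(px_per_mm=1.0)
    x_far = 60.0 if boost_safe else 10.0
    g.add_node("s1", x_mm=0.0, y_mm=0.0, px=(0.0, 0.0))
    g.add_node("s2", x_mm=2 * x_far, y_mm=0.0, px=(0.0, 2 * x_far))
    for k in range(n_corridors):
        y = 10.0 * (k - 1)
        m1, m2 = f"m1_{k}", f"m2_{k}"
        g.add_node(m1, x_mm=x_far - 3, y_mm=y, px=(y, x_far - 3))
        g.add_node(m2, x_mm=x_far + 3, y_mm=y, px=(y, x_far + 3))
        for u, v in [("s1", m1), (m1, m2), (m2, "s2")]:
            x0, y0 = g.nodes[u]["x_mm"], g.nodes[u]["y_mm"]
            x1, y1 = g.nodes[v]["x_mm"], g.nodes[v]["y_mm"]
            e = sqrt((x0 - x1) ** 2 + (y0 - y1) ** 2)
            g.add_edge(u, v, length_mm=e, euclid_mm=e, width_mm=0.8,
                       drag=e / 0.8**4)
    return g


class TestConnectingVeins:
    def test_three_corridors_counted(self):
        g = corridor_graph(3)
        n, w = connecting_veins(g, "s1", "s2")
        assert n == 3
        assert w == pytest.approx(0.8)

    def test_matches_menger_oracle(self):
        for seed in range(4):
            g = geometric_graph(seed, n=8)
            nodes = list(g.nodes)
            s, t = nodes[0], nodes[-1]
            # count on unit capacities without any boost zone (sources
            # far outside the boost radius is equivalent to no boost on
            # a graph this small, so shrink the frame instead)
            h = nx.Graph()
            h.add_edges_from(((u, v, {"capacity": 1}) for u, v in g.edges()))
            got = int(nx.maximum_flow_value(h, s, t))
            assert got == edge_disjoint_paths_oracle(g, s, t)

    def test_single_bridge_width(self):
        g = corridor_graph(1)
        n, w = connecting_veins(g, "s1", "s2")
        assert n == 1
        assert w == pytest.approx(0.8)

    def test_boosted_degree_two_source_feeds_three_corridors(self):
        # source connects by only 2 local edges into a boosted relay,
        # which fans into 3 distant corridors: the count must be 3, the
        # boost keeping the near-source bottleneck out of the way...
        g = corridor_graph(3)
        # reroute: s1 connects to a relay pair near it (within boost)
        for k in range(3):
            g.remove_edge("s1", f"m1_{k}")
        g.add_node("r1", x_mm=5.0, y_mm=2.0, px=(2.0, 5.0))
        g.add_node("r2", x_mm=5.0, y_mm=-2.0, px=(-2.0, 5.0))
        for u, v in [("s1", "r1"), ("s1", "r2")]:
            g.add_edge(u, v, length_mm=5.5, euclid_mm=5.5, width_mm=0.8,
                       drag=5.5 / 0.8**4)
        for k, r in zip(range(3), ["r1", "r2", "r1"]):
            g.add_edge(r, f"m1_{k}", length_mm=50.0, euclid_mm=50.0,
                       width_mm=0.8, drag=50.0 / 0.8**4)
        assert g.degree("s1") == 2
        n, _ = connecting_veins(g, "s1", "s2")
        assert n == 3

    def test_disconnected_sources_flagged(self):
        g = corridor_graph(2)
        g.add_node("lonely", x_mm=5.0, y_mm=30.0, px=(30.0, 5.0))
        with pytest.warns(UserWarning):
            n, w = connecting_veins(g, "s1", "lonely")
        assert n == 0


class TestIntercellPaths:
    def test_single_bridge_path_length(self):
        g = corridor_graph(1)
        plen, pdrag = intercell_paths(g, "s1", "s2")
        expect = sum(nx.dijkstra_path_length(g, "s1", "s2", weight="length_mm")
                     for _ in [0])
        assert plen == pytest.approx(expect)

    def test_length_and_drag_paths_can_differ(self):
        g = nx.Graph(px_per_mm=1.0)
        for n, (x, y) in {"a": (0, 0), "b": (10, 0), "t": (5, 5), "w": (5, -20)}.items():
            g.add_node(n, x_mm=float(x), y_mm=float(y), px=(float(y), float(x)))
        # short but thin top route; long but wide bottom route
        for u, v, L, w in [("a", "t", 7.0, 0.3), ("t", "b", 7.0, 0.3),
                           ("a", "w", 21.0, 2.0), ("w", "b", 21.0, 2.0)]:
            g.add_edge(u, v, length_mm=L, euclid_mm=L, width_mm=w, drag=L / w**4)
        plen, pdrag = intercell_paths(g, "a", "b")
        assert plen == pytest.approx(14.0)          # short thin route
        assert pdrag == pytest.approx(42.0 / 16.0)  # wide route drag

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_enumeration(self, seed):
        g = geometric_graph(seed, n=9)
        nodes = list(g.nodes)
        s, t = nodes[0], nodes[-1]
        plen, pdrag = intercell_paths(g, s, t)
        for weight, got in (("length_mm", plen), ("drag", pdrag)):
            best = min(
                sum(g[u][v][weight] for u, v in zip(p, p[1:]))
                for p in nx.all_simple_paths(g, s, t)
            )
            assert got == pytest.approx(best)


class TestSourceNodes:
    def test_nearest_nodes_to_cell_centroids(self):
        g = corridor_graph(2)
        mask = two_discs(shape=(60, 130), r=10, c1=(30, 10), c2=(30, 120))
        # px frame: hub s1 at col 0, s2 at col 120
        s1, s2 = source_nodes(g, mask)
        assert {s1, s2} == {"s1", "s2"}
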