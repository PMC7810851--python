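"""Shared fixtures and independent brute-force oracles.

The oracle helpers here deliberately avoid the library code paths they
are used to check: shortest paths by Floyd-Warshall on a dense matrix,
MSTs by exhaustive spanning-tree enumeration, betweenness by explicit
shortest-path counting, max flow by exhaustive edge-disjoint path
search, and fault tolerance by averaging over explicit removal orders.
"""

from __future__ import annotations

import itertools
from math import hypot, inf

import networkx as nx
import numpy as np
import pytest


# ---------------------------------------------------------------- fixtures

def make_frame(pixels, px_per_mm=10.0, center=None, radius=None, time_min=0.0):
    from veinnet.imaging import Frame

    pixels = np.asarray(pixels, dtype=np.uint8)
    rows, cols = pixels.shape[:2]
    if center is None:
        center = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    if radius is None:
        radius = min(rows, cols) / 2.0 - 1
    return Frame(pixels=pixels, time_min=time_min, px_per_mm=px_per_mm,
                 dish_center_px=center, dish_radius_px=radius)


def geometric_graph(seed: int, n: int = 8, extra: float = 0.3) -> nx.Graph:
    """Random connected planar-ish graph with consistent edge attributes
    (length >= euclid > 0, width > 0, drag = length / width**4)."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 10, size=(n, 2))
    cand = nx.Graph()
    for i in range(n):
        cand.add_node(i, x_mm=float(pts[i, 0]), y_mm=float(pts[i, 1]),
                      px=(pts[i, 1] * 10, pts[i, 0] * 10))
    for i, j in itertools.combinations(range(n), 2):
        cand.add_edge(i, j, w=hypot(*(pts[i] - pts[j])))
    mst = nx.minimum_spanning_tree(cand, weight="w")
    g = nx.Graph(px_per_mm=10.0)
    g.add_nodes_from(cand.nodes(data=True))
    edges = set(mst.edges())
    others = [e for e in cand.edges() if e not in edges and e[::-1] not in edges]
    k = int(extra * len(others))
    if k:
        for idx in rng.choice(len(others), size=k, replace=False):
            edges.add(others[idx])
    for i, j in edges:
        e = hypot(*(pts[i] - pts[j]))
        length = e * float(rng.uniform(1.0, 1.5))
        width = float(rng.uniform(0.3, 1.5))
        g.add_edge(i, j, length_mm=length, euclid_mm=e, width_mm=width,
                   drag=length / width**4)
    return g


@pytest.fixture
def simple_square_graph() -> nx.Graph:
    """Unit-square 4-cycle with straight unit edges of width 0.5 mm."""
    g = nx.Graph(px_per_mm=10.0)
    coords = [(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)]
    for i, (x, y) in enumerate(coords):
        g.add_node(i, x_mm=x, y_mm=y, px=(y * 10, x * 10))
    for i in range(4):
        j = (i + 1) % 4
        g.add_edge(i, j, length_mm=1.0, euclid_mm=1.0, width_mm=0.5,
                   drag=1.0 / 0.5**4)
    return g


# ------------------------------------------------------------- oracles

def floyd_warshall_oracle(g: nx.Graph, weight: str) -> dict:
    nodes = list(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    d = np.full((n, n), inf)
    np.fill_diagonal(d, 0.0)
    for u, v, data in g.edges(data=True):
        w = data[weight]
        i, j = idx[u], idx[v]
        d[i, j] = min(d[i, j], w)
        d[j, i] = min(d[j, i], w)
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return {(u, v): d[idx[u], idx[v]] for u in nodes for v in nodes}


def mst_weight_oracle(g: nx.Graph, weight: str) -> float:
    """Minimum spanning-tree weight by exhaustive edge-subset search."""
    edges = list(g.edges(data=True))
    n = g.number_of_nodes()
    best = inf
    for combo in itertools.combinations(edges, n - 1):
        t = nx.Graph()
        t.add_nodes_from(g.nodes)
        t.add_edges_from((u, v) for u, v, _ in combo)
        if nx.is_connected(t):
            best = min(best, sum(d[weight] for _, _, d in combo))
    return best


def betweenness_oracle(g: nx.Graph, weight: str) -> dict:
    """Edge betweenness (% of node pairs routed through each edge) with
    fractional splitting of equal-cost ties, by explicit enumeration of
    all shortest paths per pair."""
    nodes = list(g.nodes)
    usage = {frozenset((u, v)): 0.0 for u, v in g.edges()}
    n_pairs = len(nodes) * (len(nodes) - 1) // 2
    for s, t in itertools.combinations(nodes, 2):
        best = nx.dijkstra_path_length(g, s, t, weight=weight)
        paths = [
            p for p in nx.all_simple_paths(g, s, t)
            if abs(sum(g[a][b][weight] for a, b in zip(p, p[1:])) - best) < 1e-9
        ]
        for p in paths:
            for a, b in zip(p, p[1:]):
                usage[frozenset((a, b))] += 1.0 / len(paths)
    return {e: 100.0 * u / n_pairs for e, u in usage.items()}


def edge_disjoint_paths_oracle(g: nx.Graph, s, t) -> int:
    """Maximum number of edge-disjoint s-t paths by exhaustive
    backtracking over path systems, pruned only by the provable degree
    upper bound (so the search is still complete)."""
    bound = min(g.degree(s), g.degree(t))
    best = 0

    def recurse(h: nx.Graph, count: int) -> None:
        nonlocal best
        best = max(best, count)
        if best >= bound:
            return
        if count + min(h.degree(s), h.degree(t)) <= best:
            return
        for p in nx.all_simple_paths(h, s, t):
            h2 = h.copy()
            h2.remove_edges_from(zip(p, p[1:]))
            recurse(h2, count + 1)
            if best >= bound:
                return

    recurse(g, 0)
    return best


def ft_exhaustive_oracle(g: nx.Graph, p: float) -> float:
    """Expected fault tolerance under uniformly random removal orders,
    averaged over every permutation of the edge list."""
    edges = list(g.edges())
    n = g.number_of_nodes()
    threshold = p / 100.0 * n
    total = 0.0
    for order in itertools.permutations(range(len(edges))):
        h = g.copy()
        k_max = 0
        for k, ei in enumerate(order, start=1):
            h.remove_edge(*edges[ei])
            largest = max(len(c) for c in nx.connected_components(h))
            if largest >= threshold:
                k_max = k
            else:
                break
        total += k_max / len(edges)
    from math import factorial

    return total / factorial(len(edges))
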