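"""Cost, transport-efficiency, centrality and resiliency indexes of a
vein graph, with minimum-spanning-tree and Delaunay bounds.

The network cost (total length) is min-max normalized between the MST
of the graph's own edges (lower bound, NNL = 0) and the Delaunay
triangulation of the node coordinates (maximally connected planar upper
bound, NNL = 1).  Transport efficiency compares along-network shortest
paths with straight-line lower bounds: length efficiency
LE = (sum 1/l_ij) / (sum 1/e_ij), and drag efficiency d_ij / c_ij where
c_ij is the drag of a straight vein of 0.5 mm diameter.  Resiliency is
the fault tolerance: the fraction of edges removable while a given
percentage of nodes stays in one connected component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import sqrt

import networkx as nx
import numpy as np
from scipy.spatial import Delaunay, QhullError

REFERENCE_WIDTH_MM = 0.5  # arbitrary reference vein diameter for drag bounds


@dataclass(frozen=True)
class PathMatrices:
    """All-pairs path quantities on the largest connected component.

    Square symmetric arrays indexed like ``nodes``: along-network
    shortest path length ``l`` (mm), Euclidean inter-node distance ``e``
    (mm), minimum along-network drag ``d``, and the reference drag
    ``c = e / 0.5**4`` of a straight 0.5-mm vein.
    """

    nodes: list
    l: np.ndarray
    e: np.ndarray
    d: np.ndarray
    c: np.ndarray


@dataclass(frozen=True)
class NetworkReport:
    """Per-graph index vector."""

    n_nodes: int
    n_edges: int
    mean_degree: float
    alpha: float | None
    wiring_cost_length: float
    wiring_cost_euclid: float
    tortuosity: float
    nnl: float
    le: float
    patheff_mean: float
    patheff_cov: float
    drageff_mean: float
    drageff_cov: float
    mu_bl: float
    mu_bd: float
    ft_raw: dict = field(default_factory=dict)
    ft_norm: dict = field(default_factory=dict)


def largest_component(g: nx.Graph) -> nx.Graph:
    """The subgraph on the largest connected component (a copy)."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if nx.is_connected(g):
        return g
    comp = max(nx.connected_components(g), key=len)
    warnings.warn(
        f"graph is disconnected ({nx.number_connected_components(g)} components); "
        "metrics use the largest", stacklevel=2,
    )
    return g.subgraph(comp).copy()


def _node_xy(g: nx.Graph, n) -> tuple[float, float]:
    d = g.nodes[n]
    return d["x_mm"], d["y_mm"]


def wiring_cost_and_tortuosity(g: nx.Graph) -> tuple[float, float, float]:
    """Total edge length, total straight-chord length, and their ratio.

    Tortuosity >= 1; equals 1 when every edge is straight.
    """
    cost_length = sum(d["length_mm"] for _, _, d in g.edges(data=True))
    cost_euclid = sum(d["euclid_mm"] for _, _, d in g.edges(data=True))
    if cost_euclid <= 0:
        raise ValueError("zero Euclidean wiring cost")
    return cost_length, cost_euclid, cost_length / cost_euclid


def delaunay_graph(g: nx.Graph) -> nx.Graph:
    """Delaunay triangulation of the node coordinates, edges weighted by
    Euclidean length.  Collinear node sets degenerate to the path graph
    along the line."""
    nodes = list(g.nodes)
    if len(nodes) < 2:
        raise ValueError("need at least 2 nodes")
    pts = np.array([_node_xy(g, n) for n in nodes])
    dt = nx.Graph()
    for n in nodes:
        dt.add_node(n, **g.nodes[n])

    def connect(i, j):
        d = float(np.hypot(*(pts[i] - pts[j])))
        dt.add_edge(nodes[i], nodes[j], length_mm=d, euclid_mm=d)

    if len(nodes) == 2:
        connect(0, 1)
        return dt
    try:
        tri = Delaunay(pts)
    except QhullError:
        # collinear: chain the nodes along the line by projection order
        direction = pts[np.argmax(np.abs(pts - pts[0]).sum(axis=1))] - pts[0]
        proj = (pts - pts[0]) @ direction
        order = np.argsort(proj)
        for a, b in zip(order[:-1], order[1:]):
            connect(a, b)
        return dt
    for simplex in tri.simplices:
        for a in range(3):
            connect(simplex[a], simplex[(a + 1) % 3])
    return dt


def reference_graphs(g: nx.Graph, weight: str = "length_mm") -> tuple[nx.Graph, nx.Graph]:
    """(MST, DT) cost bounds for the graph.

    The MST is taken over the graph's own edges by the chosen weight
    (``length_mm`` or ``drag``); the DT is the Delaunay triangulation of
    the node coordinates and is weight-independent.
    """
    gc = largest_component(g)
    mst = nx.minimum_spanning_tree(gc, weight=weight)
    dt = delaunay_graph(gc)
    return mst, dt


def normalized_network_length(g: nx.Graph) -> float:
    """Map the total network length onto [0, 1] between the MST (0) and
    Delaunay (1) costs, clipping numerical overshoot."""
    gc = largest_component(g)
    mst, dt = reference_graphs(gc, weight="length_mm")
    cost_g = sum(d["length_mm"] for _, _, d in gc.edges(data=True))
    cost_mst = sum(d["length_mm"] for _, _, d in mst.edges(data=True))
    cost_dt = sum(d["length_mm"] for _, _, d in dt.edges(data=True))
    denom = cost_dt - cost_mst
    if denom <= 0:
        raise ValueError("degenerate bounds: DT cost equals MST cost")
    return float(np.clip((cost_g - cost_mst) / denom, 0.0, 1.0))


def all_pairs_paths(g: nx.Graph) -> PathMatrices:
    """Shortest-path length and drag matrices plus Euclidean and
    reference-drag bounds, on the largest connected component."""
    gc = largest_component(g)
    nodes = list(gc.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    l = np.zeros((n, n))
    d = np.zeros((n, n))
    for src, dists in nx.all_pairs_dijkstra_path_length(gc, weight="length_mm"):
        for dst, val in dists.items():
            l[idx[src], idx[dst]] = val
    for src, dists in nx.all_pairs_dijkstra_path_length(gc, weight="drag"):
        for dst, val in dists.items():
            d[idx[src], idx[dst]] = val
    pts = np.array([_node_xy(gc, nd) for nd in nodes])
    e = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    c = e / REFERENCE_WIDTH_MM**4
    return PathMatrices(nodes=nodes, l=l, e=e, d=d, c=c)


def _offdiag_pairs(pm: PathMatrices) -> np.ndarray:
    n = len(pm.nodes)
    iu = np.triu_indices(n, k=1)
    return iu


def length_efficiency(pm: PathMatrices) -> tuple[float, float, float]:
    """LE = (sum 1/l_ij) / (sum 1/e_ij) over unordered pairs, and the
    mean / coefficient of variation of the per-pair efficiencies
    e_ij / l_ij.  Coincident-node pairs (e = 0) are excluded."""
    iu = _offdiag_pairs(pm)
    l = pm.l[iu]
    e = pm.e[iu]
    keep = e > 0
    if keep.sum() < len(e):
        warnings.warn("coincident node pairs excluded from efficiency sums", stacklevel=2)
    l, e = l[keep], e[keep]
    if len(l) == 0:
        raise ValueError("no valid node pairs")
    le = float((1.0 / l).sum() / (1.0 / e).sum())
    ratios = e / l
    mean = float(ratios.mean())
    cov = float(ratios.std() / mean) if mean > 0 else 0.0
    return le, mean, cov


def drag_efficiency(pm: PathMatrices) -> tuple[float, float]:
    """Mean and COV of the drag efficiencies d_ij / c_ij.

    The 0.5-mm reference shifts and stretches the values but keeps the
    ordering across graphs, so these statistics are comparative.
    """
    iu = _offdiag_pairs(pm)
    d = pm.d[iu]
    c = pm.c[iu]
    keep = c > 0
    d, c = d[keep], c[keep]
    if len(d) == 0:
        raise ValueError("no valid node pairs")
    ratios = d / c
    mean = float(ratios.mean())
    cov = float(ratios.std() / mean) if mean > 0 else 0.0
    return mean, cov


def edge_betweenness(
    g: nx.Graph, weight: str = "length_mm"
) -> tuple[dict, float]:
    """Per-edge betweenness as the percentage of all inter-node
    shortest paths using the edge (equal-cost ties split fractionally),
    and mu = the mean over edges."""
    gc = largest_component(g)
    bc = nx.edge_betweenness_centrality(gc, normalized=True, weight=weight)
    percent = {e: 100.0 * v for e, v in bc.items()}
    mu = float(np.mean(list(percent.values()))) if percent else 0.0
    return percent, mu


def _ft_single(
    edges: list, n_nodes: int, threshold_nodes: float, order: np.ndarray,
    uf_edges_of: dict,
) -> int:
    """Edges removable (following ``order``) while the largest component
    keeps >= threshold_nodes nodes.  Computed by adding edges back in
    reverse with a union-find."""
    m = len(edges)
    parent = list(range(n_nodes))
    size = [1] * n_nodes

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    largest = 1 if n_nodes else 0
    # sizes_after_k[k] = largest component size after removing the first
    # k edges of `order`; build from fully-removed state backwards.
    sizes = [0] * (m + 1)
    sizes[m] = largest
    for k in range(m - 1, -1, -1):
        u, v = edges[order[k]]
        ra, rb = find(uf_edges_of[u]), find(uf_edges_of[v])
        if ra != rb:
            if size[ra] < size[rb]:
                ra, rb = rb, ra
            parent[rb] = ra
            size[ra] += size[rb]
            largest = max(largest, size[ra])
        sizes[k] = largest
    k_max = 0
    for k in range(m + 1):
        if sizes[k] >= threshold_nodes:
            k_max = k
        else:
            break
    return k_max


def fault_tolerance_raw(
    g: nx.Graph, percents: tuple[int, ...] = (25, 50, 75),
    reps: int = 30, rng: np.random.Generator | None = None,
) -> dict[int, float]:
    """Random-removal fault tolerance for each connectivity percentage.

    Per realization, edges are removed in a uniformly random order; the
    FT is the maximum fraction of edges removable while the largest
    component still holds at least p% of the original nodes (inclusive
    threshold).  Averaged over ``reps`` realizations; the same removal
    orders serve all percentages, so FT(25) >= FT(50) >= FT(75) holds
    realization-wise.
    """
    rng = rng or np.random.default_rng()
    nodes = list(g.nodes)
    n = len(nodes)
    nid = {nd: i for i, nd in enumerate(nodes)}
    edges = list(g.edges())
    m = len(edges)
    if m == 0:
        raise ValueError("graph has no edges")
    totals = {p: 0.0 for p in percents}
    for _ in range(reps):
        order = rng.permutation(m)
        for p in percents:
            k = _ft_single(edges, n, p / 100.0 * n, order, nid)
            totals[p] += k / m
    return {p: totals[p] / reps for p in percents}


def fault_tolerance_random(
    g: nx.Graph, percents: tuple[int, ...] = (25, 50, 75),
    reps: int = 30, rng_seed: int | None = None,
) -> tuple[dict[int, float], dict[int, float]]:
    """(FT_raw, FT_norm) where FT_norm maps FT between the MST (0) and
    the Delaunay triangulation (1) of the graph, clipped to [0, 1].

    The same random-number stream drives the removal orders for the
    graph and both bounds (common random numbers): a graph that *is*
    its MST or its DT then maps exactly to 0 or 1.
    """
    gc = largest_component(g)
    if rng_seed is None:
        rng_seed = int(np.random.default_rng().integers(2**31))
    ft_g = fault_tolerance_raw(gc, percents, reps, np.random.default_rng(rng_seed))
    mst, dt = reference_graphs(gc, weight="length_mm")
    ft_mst = fault_tolerance_raw(mst, percents, reps, np.random.default_rng(rng_seed))
    ft_dt = fault_tolerance_raw(dt, percents, reps, np.random.default_rng(rng_seed))
    ft_norm = {}
    for p in percents:
        denom = ft_dt[p] - ft_mst[p]
        if denom <= 0:
            warnings.warn(f"degenerate FT bounds at p={p}", stacklevel=2)
            ft_norm[p] = float("nan")
        else:
            ft_norm[p] = float(np.clip((ft_g[p] - ft_mst[p]) / denom, 0.0, 1.0))
    return ft_g, ft_norm


def fault_tolerance_decay(g: nx.Graph, order: str = "worst") -> np.ndarray:
    """Connectivity decay under rank-ordered edge removal.

    Edges are ranked once by drag betweenness; the ``worst`` scenario
    removes the highest-betweenness (most important) edges first, the
    ``best`` removes the least important first.  Returns, for
    k = 1..100 (% of edges removed, ceil), the largest-component size as
    a percentage of the original node count.
    """
    if order not in {"worst", "best"}:
        raise ValueError("order must be 'worst' or 'best'")
    gc = largest_component(g)
    bc, _ = edge_betweenness(gc, weight="drag")
    ranked = sorted(bc, key=lambda e: (bc[e], e), reverse=(order == "worst"))
    n = gc.number_of_nodes()
    m = gc.number_of_edges()
    curve = np.empty(100)
    for i, k in enumerate(range(1, 101)):
        n_remove = int(np.ceil(k / 100.0 * m))
        h = gc.copy()
        h.remove_edges_from(ranked[:n_remove])
        largest = max((len(c) for c in nx.connected_components(h)), default=0)
        curve[i] = 100.0 * largest / n
    return curve


def network_report(
    g: nx.Graph, reps: int = 30, rng_seed: int | None = None
) -> NetworkReport:
    """Compute the full per-graph index vector on the largest component."""
    from veinnet.graphs import connectivity_indexes

    gc = largest_component(g)
    mean_degree, _, alpha = connectivity_indexes(gc)
    cost_l, cost_e, tort = wiring_cost_and_tortuosity(gc)
    nnl = normalized_network_length(gc)
    pm = all_pairs_paths(gc)
    le, pe_mean, pe_cov = length_efficiency(pm)
    de_mean, de_cov = drag_efficiency(pm)
    _, mu_bl = edge_betweenness(gc, weight="length_mm")
    _, mu_bd = edge_betweenness(gc, weight="drag")
    ft_raw, ft_norm = fault_tolerance_random(gc, reps=reps, rng_seed=rng_seed)
    return NetworkReport(
        n_nodes=gc.number_of_nodes(),
        n_edges=gc.number_of_edges(),
        mean_degree=mean_degree,
        alpha=alpha,
        wiring_cost_length=cost_l,
        wiring_cost_euclid=cost_e,
        tortuosity=tort,
        nnl=nnl,
        le=le,
        patheff_mean=pe_mean,
        patheff_cov=pe_cov,
        drageff_mean=de_mean,
        drageff_cov=de_cov,
        mu_bl=mu_bl,
        mu_bd=mu_bd,
        ft_raw=ft_raw,
        ft_norm=ft_norm,
    )
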