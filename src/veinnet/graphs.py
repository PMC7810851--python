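"""Conversion of a skeletonized cell into an undirected vein graph.

Nodes are the branch points (skeleton pixels with three or more
neighbours, clustered into junction blobs) and the end points of the
medial axis; edges are the pixel paths between them.  Each edge carries
its traced length, the Euclidean chord between its parent nodes, its
mean vein width, and its drag — length divided by the fourth power of
width, a Poiseuille-like resistance proxy.
"""

from __future__ import annotations

from math import sqrt

import networkx as nx
import numpy as np
from scipy import ndimage as ndi

from veinnet.morphology import SkeletonField

_EIGHT = np.ones((3, 3), dtype=int)

_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _step(a: tuple[int, int], b: tuple[int, int]) -> float:
    return 1.0 if (a[0] == b[0] or a[1] == b[1]) else sqrt(2.0)


def _path_length_px(path: list[tuple[int, int]]) -> float:
    return float(sum(_step(path[i], path[i + 1]) for i in range(len(path) - 1)))


def extract_graph(skel: SkeletonField) -> nx.MultiGraph:
    """Trace the vein graph from a skeleton with half-width field.

    Returns a multigraph (parallel edges and self-loops may exist before
    :func:`simplify_graph`).  Node attributes: ``x_mm``, ``y_mm``,
    ``px`` (row, col), ``kind``; edge attributes: ``length_mm``,
    ``euclid_mm``, ``width_mm``, ``drag``, ``path`` (pixel trace).
    Isolated cycles receive a single anchor node at their
    topmost-leftmost pixel.
    """
    S = skel.skeleton.astype(bool)
    if not S.any():
        raise ValueError("empty skeleton")
    ppm = skel.px_per_mm
    nbr_count = ndi.convolve(S.astype(int), _EIGHT, mode="constant") - S.astype(int)
    nbr_count[~S] = 0
    node_px = S & ((nbr_count >= 3) | (nbr_count <= 1))

    # Anchor nodes for components containing no branch/end pixel (rings).
    comp_labels, n_comp = ndi.label(S, structure=_EIGHT)
    for ci in range(1, n_comp + 1):
        comp = comp_labels == ci
        if not (node_px & comp).any():
            rs, cs = np.nonzero(comp)
            k = np.lexsort((cs, rs))[0]  # topmost, then leftmost
            node_px[rs[k], cs[k]] = True

    node_labels, n_nodes = ndi.label(node_px, structure=_EIGHT)
    g = nx.MultiGraph(px_per_mm=ppm)
    centroids = ndi.center_of_mass(node_px, node_labels, range(1, n_nodes + 1))
    for nid, (r, c) in enumerate(centroids, start=1):
        g.add_node(nid, x_mm=c / ppm, y_mm=r / ppm, px=(r, c), kind="vein")

    half = skel.half_width

    def add_edge(u: int, v: int, path: list[tuple[int, int]]) -> None:
        length_mm = _path_length_px(path) / ppm
        pu, pv = g.nodes[u]["px"], g.nodes[v]["px"]
        euclid_mm = sqrt((pu[0] - pv[0]) ** 2 + (pu[1] - pv[1]) ** 2) / ppm
        width_mm = 2.0 * float(np.mean([half[p] for p in path]))
        drag = length_mm / width_mm**4 if width_mm > 0 else np.inf
        g.add_edge(
            u, v, length_mm=length_mm, euclid_mm=euclid_mm,
            width_mm=width_mm, drag=drag, path=path,
        )

    visited = np.zeros_like(S, dtype=bool)
    direct = set()  # node-region pairs already joined by a zero-interior edge
    node_rows, node_cols = np.nonzero(node_px)
    rows, cols = S.shape
    for r0, c0 in zip(node_rows, node_cols):
        u = node_labels[r0, c0]
        for dr, dc in _NEIGHBOURS:
            r1, c1 = r0 + dr, c0 + dc
            if not (0 <= r1 < rows and 0 <= c1 < cols) or not S[r1, c1]:
                continue
            if node_px[r1, c1]:
                v = node_labels[r1, c1]
                if v != u:
                    key = (min(u, v), max(u, v))
                    if key not in direct:
                        direct.add(key)
                        add_edge(u, v, [(r0, c0), (r1, c1)])
                continue
            if visited[r1, c1]:
                continue
            # walk the path until the next node pixel
            path = [(r0, c0), (r1, c1)]
            visited[r1, c1] = True
            prev, cur = (r0, c0), (r1, c1)
            end_node = None
            while True:
                nxts, node_hits = [], []
                for dr2, dc2 in _NEIGHBOURS:
                    r2, c2 = cur[0] + dr2, cur[1] + dc2
                    if not (0 <= r2 < rows and 0 <= c2 < cols) or not S[r2, c2]:
                        continue
                    if (r2, c2) == prev:
                        continue
                    if node_px[r2, c2]:
                        node_hits.append((r2, c2))
                    elif not visited[r2, c2]:
                        nxts.append((r2, c2))
                if node_hits:
                    # avoid re-entering the start blob via a pixel adjacent
                    # to the start pixel (diagonal shortcut), unless the
                    # path is genuinely a loop
                    node_hits.sort()
                    end_node = node_hits[0]
                    path.append(end_node)
                    break
                if not nxts:
                    end_node = None  # dangling (shouldn't happen on clean skeletons)
                    break
                nxts.sort()
                nxt = nxts[0]
                path.append(nxt)
                visited[nxt] = True
                prev, cur = cur, nxt
            if end_node is None:
                continue
            v = node_labels[end_node]
            add_edge(u, v, path)

    _merge_close_nodes(g, min_dist_px=2.0, ppm=ppm)
    _prune_spurs(g, ppm=ppm)
    # node merging moves centroids: refresh chords and keep the traced
    # length no shorter than the straight chord so l >= e always holds
    for u, v, data in g.edges(data=True):
        pu, pv = g.nodes[u]["px"], g.nodes[v]["px"]
        euclid = sqrt((pu[0] - pv[0]) ** 2 + (pu[1] - pv[1]) ** 2) / ppm
        data["euclid_mm"] = euclid
        data["length_mm"] = max(data["length_mm"], euclid)
        if data["width_mm"] > 0:
            data["drag"] = data["length_mm"] / data["width_mm"] ** 4
    return g


def _merge_close_nodes(g: nx.MultiGraph, min_dist_px: float, ppm: float) -> None:
    """Contract nodes closer than ``min_dist_px`` (junction-blob relics)."""
    nodes = list(g.nodes)
    parent = {n: n for n in nodes}

    def find(n):
        while parent[n] != n:
            parent[n] = parent[parent[n]]
            n = parent[n]
        return n

    for i, u in enumerate(nodes):
        pu = g.nodes[u]["px"]
        for v in nodes[i + 1:]:
            pv = g.nodes[v]["px"]
            if (pu[0] - pv[0]) ** 2 + (pu[1] - pv[1]) ** 2 < min_dist_px**2:
                parent[find(v)] = find(u)
    groups: dict[int, list[int]] = {}
    for n in nodes:
        groups.setdefault(find(n), []).append(n)
    for root, members in groups.items():
        if len(members) == 1:
            continue
        rs = np.mean([g.nodes[m]["px"][0] for m in members])
        cs = np.mean([g.nodes[m]["px"][1] for m in members])
        for m in members:
            if m != root:
                nx.contracted_nodes(g, root, m, self_loops=True, copy=False)
        g.nodes[root]["px"] = (rs, cs)
        g.nodes[root]["x_mm"] = cs / ppm
        g.nodes[root]["y_mm"] = rs / ppm
        g.nodes[root].pop("contraction", None)


def _prune_spurs(g: nx.MultiGraph, ppm: float) -> None:
    """Drop terminal thinning artifacts: edges shorter than 2 px and
    thinner than 1 px ending in a degree-1 node."""
    changed = True
    while changed:
        changed = False
        for u, v, k, data in list(g.edges(keys=True, data=True)):
            if u == v:
                continue
            if data["length_mm"] * ppm < 2.0 and data["width_mm"] * ppm < 1.0:
                if g.degree(u) == 1 or g.degree(v) == 1:
                    g.remove_edge(u, v, key=k)
                    changed = True
        isolated = [n for n in g.nodes if g.degree(n) == 0]
        if isolated and g.number_of_nodes() > len(isolated):
            g.remove_nodes_from(isolated)


def contract_degree_two(g: nx.Graph) -> nx.Graph:
    """Smooth out degree-2 nodes, chaining their incident edges.

    Useful when comparing a planted graph (which may contain degree-2
    waypoints) with an extracted one, where such nodes are invisible:
    skeleton tracing only recognises branch and end points.  Lengths
    add; widths combine length-weighted; drag is recomputed.
    """
    h = g.copy()
    changed = True
    while changed:
        changed = False
        for n in list(h.nodes):
            if h.degree(n) != 2:
                continue
            nbrs = list(h.neighbors(n))
            if len(nbrs) != 2:
                continue  # self-loop
            u, v = nbrs
            if u == v or h.has_edge(u, v):
                continue  # keep cycle-closing waypoints
            d1 = h[n][u]
            d2 = h[n][v]
            length = d1["length_mm"] + d2["length_mm"]
            width = (
                d1["width_mm"] * d1["length_mm"] + d2["width_mm"] * d2["length_mm"]
            ) / length
            pu, pv = h.nodes[u]["px"], h.nodes[v]["px"]
            euclid = sqrt((pu[0] - pv[0]) ** 2 + (pu[1] - pv[1]) ** 2) / h.graph.get(
                "px_per_mm", 1.0
            )
            h.add_edge(u, v, length_mm=length, euclid_mm=euclid, width_mm=width,
                       drag=length / width**4)
            h.remove_node(n)
            changed = True
    return h


def simplify_graph(g: nx.MultiGraph | nx.Graph) -> nx.Graph:
    """Remove self-loops and collapse parallel edges, keeping the
    minimum-drag edge of each parallel bundle.  Idempotent."""
    out = nx.Graph(**g.graph)
    out.add_nodes_from(g.nodes(data=True))
    if g.is_multigraph():
        edge_iter = ((u, v, d) for u, v, _, d in g.edges(keys=True, data=True))
    else:
        edge_iter = g.edges(data=True)
    for u, v, data in edge_iter:
        if u == v:
            continue
        if out.has_edge(u, v) and out[u][v]["drag"] <= data["drag"]:
            continue
        out.add_edge(u, v, **data)
    return out


def classify_nodes(
    g: nx.Graph,
    pseudopod_mask: np.ndarray | None = None,
    initial_cell_mask: np.ndarray | None = None,
) -> nx.Graph:
    """Assign each node a kind: ``initial_cell`` takes precedence over
    ``pseudopod``; everything else is ``vein``.  Masks are rasters in
    the graph's pixel frame."""
    shape = None
    for m in (pseudopod_mask, initial_cell_mask):
        if m is not None:
            shape = m.shape
    for n, data in g.nodes(data=True):
        r = int(round(data["px"][0]))
        c = int(round(data["px"][1]))
        if shape is not None and not (0 <= r < shape[0] and 0 <= c < shape[1]):
            raise ValueError(f"node {n} at {(r, c)} lies outside the raster")
        kind = "vein"
        if pseudopod_mask is not None and pseudopod_mask[r, c]:
            kind = "pseudopod"
        if initial_cell_mask is not None and initial_cell_mask[r, c]:
            kind = "initial_cell"
        data["kind"] = kind
    return g


def connectivity_indexes(
    g: nx.Graph,
) -> tuple[float, np.ndarray, float | None]:
    """Mean node degree, degree histogram and the alpha (cycle-density)
    index ``(E - N + 1) / (2N - 5)``.

    Alpha is 0 for trees and 1 for maximally connected planar graphs
    (e.g. Delaunay triangulations); it is undefined (None) for N < 3.
    """
    n = g.number_of_nodes()
    e = g.number_of_edges()
    if n == 0:
        raise ValueError("empty graph")
    degrees = np.array([d for _, d in g.degree()])
    hist = np.bincount(degrees)
    mean_degree = 2.0 * e / n
    alpha = (e - n + 1) / (2 * n - 5) if n >= 3 else None
    return mean_degree, hist, alpha
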