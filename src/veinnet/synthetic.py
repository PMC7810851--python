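"""Ground-truthed synthetic scenes for validating the pipeline.

Real dishes show a light-yellow cell on a pale background whose vein
network has many short, thin veins and few long, thick ones (a
right-skewed, log-logistic-like width distribution), fan-shaped
pseudopods at the growth frontier, and enclosed empty regions where
loops close.  The generator emulates that structure with full knowledge
of the truth: it plants a planar loopy graph between the minimum
spanning tree and the Delaunay triangulation of random dish points,
assigns log-logistic vein widths that decay away from the root,
rasterizes the veins as capsules, and renders a noisy RGB photograph.
Growth and two-cell fusion sequences expand the same scene along the
network distance from the root, so every frame's mask, graph and merge
frame are known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import ceil, hypot, sqrt

import networkx as nx
import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import Delaunay
from scipy.stats import fisk

from veinnet.imaging import CellMask, Frame

BACKGROUND_RGB = np.array([235.0, 235.0, 230.0])
SLIME_RGB = np.array([220.0, 210.0, 140.0])
OUTSIDE_RGB = np.array([70.0, 70.0, 70.0])


@dataclass(frozen=True)
class SceneParams:
    """Generator knobs (lengths in mm, image in pixels).

    Defaults describe a single cell that has explored a ~14 mm-radius
    patch of a 90 mm dish: ~45 graph nodes, log-logistic widths
    (shape 3, scale 0.55 mm, so the distribution is right-skewed), a
    loop fraction (``hole_density``) tuned so the mean node degree sits
    near the branch-dominated value of biological transport networks
    (about 2.7), three pseudopod fans at the frontier, and mild sensor
    noise.
    """

    n_nodes: int = 45
    cell_radius_mm: float = 14.0
    width_shape: float = 3.0
    width_scale_mm: float = 0.55
    width_min_mm: float = 0.35
    width_max_mm: float = 2.2
    trunk_boost: float = 1.8
    pseudopod_count: int = 3
    pseudopod_radius_mm: float = 2.5
    hole_density: float = 0.18
    nnl_range: tuple[float, float] | None = None
    noise_sd: float = 4.0
    px_per_mm: float = 5.5
    image_size: int = 512
    dish_radius_mm: float = 45.0
    initial_cell_radius_mm: float = 6.5
    include_initial_cell: bool = True
    min_node_sep_mm: float = 2.2


@dataclass(frozen=True)
class SyntheticScene:
    """A rendered frame plus its exact ground truth."""

    frame: Frame
    truth_mask: CellMask
    truth_graph: nx.Graph
    pseudopod_mask: np.ndarray
    initial_cell_mask: np.ndarray
    params: SceneParams
    seed: int

    @property
    def truth_total_length_mm(self) -> float:
        return sum(d["length_mm"] for _, _, d in self.truth_graph.edges(data=True))


def _sample_points(
    rng: np.random.Generator, n: int, center_mm: np.ndarray, radius_mm: float,
    min_sep_mm: float,
) -> np.ndarray:
    """Blue-noise-ish points in a disc by rejection sampling."""
    pts: list[np.ndarray] = []
    attempts = 0
    sep = min_sep_mm
    while len(pts) < n and attempts < 20000:
        attempts += 1
        r = radius_mm * sqrt(rng.uniform())
        th = rng.uniform(0, 2 * np.pi)
        p = center_mm + r * np.array([np.cos(th), np.sin(th)])
        if all(hypot(*(p - q)) >= sep for q in pts):
            pts.append(p)
        if attempts % 4000 == 0:
            sep *= 0.9  # relax if the disc is too crowded
    return np.array(pts)


def _planar_graph(
    rng: np.random.Generator, pts: np.ndarray, hole_density: float,
    nnl_range: tuple[float, float] | None,
) -> nx.Graph:
    """MST of the Delaunay edges plus extra loop edges.

    With ``nnl_range`` set, shortest candidate edges are added until the
    straight-line normalized network length enters the range (error if
    infeasible); otherwise a ``hole_density`` fraction of the remaining
    Delaunay edges is added at random.
    """
    tri = Delaunay(pts)
    cand = nx.Graph()
    cand.add_nodes_from(range(len(pts)))
    for simplex in tri.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            cand.add_edge(i, j, length_mm=float(hypot(*(pts[i] - pts[j]))))
    mst = nx.minimum_spanning_tree(cand, weight="length_mm")
    g = nx.Graph()
    g.add_nodes_from(cand.nodes)
    g.add_edges_from(mst.edges(data=True))
    rest = [
        (u, v, d) for u, v, d in cand.edges(data=True) if not g.has_edge(u, v)
    ]
    if nnl_range is not None:
        lo, hi = nnl_range
        cost_mst = sum(d["length_mm"] for _, _, d in mst.edges(data=True))
        cost_dt = sum(d["length_mm"] for _, _, d in cand.edges(data=True))
        span = cost_dt - cost_mst
        rest.sort(key=lambda t: t[2]["length_mm"])
        cost = cost_mst
        nnl = 0.0
        for u, v, d in rest:
            if nnl >= lo:
                break
            if (cost + d["length_mm"] - cost_mst) / span > hi:
                break
            g.add_edge(u, v, **d)
            cost += d["length_mm"]
            nnl = (cost - cost_mst) / span
        if not (lo <= nnl <= hi):
            raise ValueError(f"NNL target {nnl_range} infeasible (reached {nnl:.3f})")
        return g
    n_extra = int(round(hole_density * len(rest)))
    if n_extra and rest:
        idx = rng.choice(len(rest), size=min(n_extra, len(rest)), replace=False)
        for k in idx:
            u, v, d = rest[k]
            g.add_edge(u, v, **d)
    return g


def _assign_widths(
    rng: np.random.Generator, g: nx.Graph, pts: np.ndarray, root: int,
    p: SceneParams,
) -> None:
    """Log-logistic widths, thicker near the root (trunk veins)."""
    depth = nx.single_source_shortest_path_length(g, root)
    max_depth = max(depth.values()) or 1
    for u, v, d in g.edges(data=True):
        dd = min(depth[u], depth[v]) / max_depth
        boost = 1.0 + (p.trunk_boost - 1.0) * np.exp(-3.0 * dd)
        w = float(fisk.rvs(p.width_shape, scale=p.width_scale_mm, random_state=rng))
        d["width_mm"] = float(np.clip(w * boost, p.width_min_mm, p.width_max_mm))
        d["drag"] = d["length_mm"] / d["width_mm"] ** 4


def _paint_segment(
    scale: np.ndarray, mask: np.ndarray, p0: np.ndarray, p1: np.ndarray,
    width_mm: float, ppm: float, darkness: float,
) -> None:
    """Rasterize a capsule (thick segment) into mask and darkness-scale."""
    half_px = width_mm * ppm / 2.0
    r0 = np.array([p0[1] * ppm, p0[0] * ppm])  # (row, col) from (x, y)
    r1 = np.array([p1[1] * ppm, p1[0] * ppm])
    lo = np.floor(np.minimum(r0, r1) - half_px - 1).astype(int)
    hi = np.ceil(np.maximum(r0, r1) + half_px + 2).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, mask.shape)
    if (hi <= lo).any():
        return
    rr, cc = np.mgrid[lo[0]:hi[0], lo[1]:hi[1]]
    pt = np.stack([rr, cc], axis=-1).astype(float)
    seg = r1 - r0
    seg_len2 = float(seg @ seg)
    if seg_len2 == 0:
        dist = np.hypot(*(pt - r0).transpose(2, 0, 1))
    else:
        t = np.clip(((pt - r0) @ seg) / seg_len2, 0.0, 1.0)
        proj = r0 + t[..., None] * seg
        dist = np.hypot(*(pt - proj).transpose(2, 0, 1))
    hit = dist <= half_px
    sub = (slice(lo[0], hi[0]), slice(lo[1], hi[1]))
    mask[sub] |= hit
    scale[sub] = np.where(hit, np.minimum(scale[sub], darkness), scale[sub])


def _paint_disc(
    scale: np.ndarray, mask: np.ndarray, center_mm: np.ndarray, radius_mm: float,
    ppm: float, darkness: float,
) -> None:
    _paint_segment(scale, mask, center_mm, center_mm, 2 * radius_mm, ppm, darkness)


def _render(
    mask: np.ndarray, scale: np.ndarray, valid: np.ndarray,
    rng: np.random.Generator, noise_sd: float,
) -> np.ndarray:
    img = np.empty(mask.shape + (3,), dtype=float)
    img[:] = OUTSIDE_RGB
    img[valid] = BACKGROUND_RGB
    fg = mask & valid
    img[fg] = SLIME_RGB[None, :] * scale[fg, None]
    img += rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _truth_graph_from(
    g: nx.Graph, pts: np.ndarray, ppm: float, edges=None
) -> nx.Graph:
    out = nx.Graph(px_per_mm=ppm)
    edge_list = list(g.edges(data=True)) if edges is None else edges
    used = {u for u, v, _ in edge_list} | {v for _, v, _ in edge_list}
    for n in used:
        x, y = pts[n]
        out.add_node(n, x_mm=float(x), y_mm=float(y), px=(y * ppm, x * ppm), kind="vein")
    for u, v, d in edge_list:
        out.add_edge(u, v, length_mm=d["length_mm"], euclid_mm=d["length_mm"],
                     width_mm=d["width_mm"], drag=d["drag"])
    return out


def _scene_geometry(params: SceneParams, seed: int, center_mm=None):
    """Sample points, graph, widths; returns (rng, pts, g, root)."""
    rng = np.random.default_rng([seed, 2024])
    size_mm = params.image_size / params.px_per_mm
    if center_mm is None:
        center_mm = np.array([size_mm / 2, size_mm / 2])
    pts = _sample_points(rng, params.n_nodes, center_mm, params.cell_radius_mm,
                         params.min_node_sep_mm)
    if len(pts) < 4:
        raise ValueError("too few points sampled; loosen the parameters")
    g = _planar_graph(rng, pts, params.hole_density, params.nnl_range)
    root = int(np.argmin(np.hypot(*(pts - center_mm).T)))
    _assign_widths(rng, g, pts, root, params)
    return rng, pts, g, root, center_mm


def _width_darkness(w_mm: float, params: SceneParams) -> float:
    # thicker veins carry more pigment: darker rendering
    return 1.0 - 0.25 * min(1.0, w_mm / params.width_max_mm)


def _rasterize(
    params: SceneParams, pts: np.ndarray, edge_list, pseudopods, initial_center,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    n_px = params.image_size
    ppm = params.px_per_mm
    mask = np.zeros((n_px, n_px), dtype=bool)
    scale = np.ones((n_px, n_px), dtype=float)
    for u, v, d in edge_list:
        _paint_segment(scale, mask, pts[u], pts[v], d["width_mm"], ppm,
                       _width_darkness(d["width_mm"], params))
    pseudo_mask = np.zeros_like(mask)
    for center, radius in pseudopods:
        _paint_disc(scale, pseudo_mask, center, radius, ppm, 0.78)
    init_mask = np.zeros_like(mask)
    if initial_center is not None and params.include_initial_cell:
        _paint_disc(scale, init_mask, initial_center,
                    params.initial_cell_radius_mm, ppm, 0.72)
    mask |= pseudo_mask | init_mask
    return mask, scale, pseudo_mask, init_mask


def _frame_of(params: SceneParams, img: np.ndarray, time_min: float) -> Frame:
    c = (params.image_size - 1) / 2.0
    return Frame(
        pixels=img, time_min=time_min, px_per_mm=params.px_per_mm,
        dish_center_px=(c, c), dish_radius_px=params.dish_radius_mm * params.px_per_mm,
    )


def _valid_disc(params: SceneParams) -> np.ndarray:
    n = params.image_size
    c = (n - 1) / 2.0
    rr, cc = np.ogrid[:n, :n]
    r_px = params.dish_radius_mm * params.px_per_mm
    return (rr - c) ** 2 + (cc - c) ** 2 <= r_px**2


def generate_vein_graph(
    params: SceneParams | None = None, seed: int = 0
) -> nx.Graph:
    """Just the planted vein graph of :func:`generate_vein_scene`,
    skipping rasterization — convenient for graph-metric ensembles."""
    params = params or SceneParams()
    _, pts, g, _, _ = _scene_geometry(params, seed)
    return _truth_graph_from(g, pts, params.px_per_mm)


def generate_vein_scene(params: SceneParams | None = None, seed: int = 0) -> SyntheticScene:
    """One static scene: a loopy planar vein network with pseudopod fans
    and an initial-cell disc, rendered as a noisy dish photograph.

    Bit-identical for fixed (params, seed).
    """
    params = params or SceneParams()
    rng, pts, g, root, center = _scene_geometry(params, seed)
    # pseudopods at the frontier: farthest nodes from the root
    order = np.argsort(-np.hypot(*(pts - center).T))
    pseudopods = [
        (pts[int(order[i])], params.pseudopod_radius_mm)
        for i in range(min(params.pseudopod_count, len(order)))
    ]
    mask, scale, pseudo_mask, init_mask = _rasterize(
        params, pts, list(g.edges(data=True)), pseudopods, center
    )
    valid = _valid_disc(params)
    mask &= valid
    img = _render(mask, scale, valid, rng, params.noise_sd)
    truth = _truth_graph_from(g, pts, params.px_per_mm)
    return SyntheticScene(
        frame=_frame_of(params, img, 0.0),
        truth_mask=CellMask(foreground=mask, px_per_mm=params.px_per_mm),
        truth_graph=truth,
        pseudopod_mask=pseudo_mask,
        initial_cell_mask=init_mask,
        params=params, seed=seed,
    )


def _growth_thresholds(
    g: nx.Graph, root: int, n_frames: int
) -> tuple[dict, list[float]]:
    """Network distance of each node from the root and per-frame radii
    chosen as distance quantiles, so every frame adds new veins."""
    dist = nx.single_source_dijkstra_path_length(g, root, weight="length_mm")
    vals = np.sort(np.array(list(dist.values())))
    qs = np.linspace(0.05, 1.0, n_frames)
    radii = [float(np.quantile(vals, q)) for q in qs]
    return dist, radii


def generate_growth_sequence(
    params: SceneParams | None = None, seed: int = 0, n_frames: int = 8,
    frame_interval_min: float = 60.0,
) -> list[SyntheticScene]:
    """Expansion time-lapse: the network advances along its own veins.

    Frame t contains every edge whose endpoints lie within the t-th
    quantile of network distance from the root, so the covered area is
    strictly increasing and each frame's truth is exact.

    The default parameters use a larger network (~110 nodes over a
    28 mm radius) than the static scene, so the final covered area
    exceeds four times the initial-cell area — the span the
    normalized-area analysis samples.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if params is None:
        params = replace(SceneParams(), n_nodes=110, cell_radius_mm=28.0)
    rng, pts, g, root, center = _scene_geometry(params, seed)
    dist, radii = _growth_thresholds(g, root, n_frames)
    valid = _valid_disc(params)
    scenes = []
    for t, r in enumerate(radii):
        edges = [
            (u, v, d) for u, v, d in g.edges(data=True)
            if dist[u] <= r and dist[v] <= r
        ]
        frontier = [n for n in g.nodes if dist[n] <= r]
        order = sorted(frontier, key=lambda n: -dist[n])
        k = min(params.pseudopod_count, len(order))
        pseudopods = [(pts[n], params.pseudopod_radius_mm) for n in order[:k]] if t > 0 else []
        mask, scale, pseudo_mask, init_mask = _rasterize(
            params, pts, edges, pseudopods, center
        )
        mask &= valid
        img = _render(mask, scale, valid, rng, params.noise_sd)
        scenes.append(SyntheticScene(
            frame=_frame_of(params, img, t * frame_interval_min),
            truth_mask=CellMask(foreground=mask, px_per_mm=params.px_per_mm),
            truth_graph=_truth_graph_from(g, pts, params.px_per_mm, edges),
            pseudopod_mask=pseudo_mask,
            initial_cell_mask=init_mask,
            params=params, seed=seed,
        ))
    return scenes


@dataclass(frozen=True)
class FusionTruth:
    """Planted ground truth of a fusion sequence."""

    merge_frame: int
    n_corridors: int
    corridor_widths_mm: list[float]
    cell_centers_mm: tuple[tuple[float, float], tuple[float, float]]


def generate_fusion_sequence(
    params: SceneParams | None = None, seed: int = 0, merge_frame: int = 5,
    n_corridors: int = 2, n_frames: int = 12, frame_interval_min: float = 15.0,
    corridor_thinning: float = 0.0,
) -> tuple[list[SyntheticScene], FusionTruth]:
    """Two cells growing toward each other, bridged by exactly
    ``n_corridors`` vein corridors from ``merge_frame`` on.

    The cells are rooted near opposite dish edges so the mid-gap
    corridor segments sit more than 25 mm from both initial-cell
    centres, outside the max-flow capacity-boost zone.  With
    ``corridor_thinning`` > 0 the corridor widths shrink linearly by
    that fraction between the merge frame and the last frame.
    """
    if n_corridors < 1:
        raise ValueError("need at least one corridor")
    if not 0 <= merge_frame < n_frames:
        raise ValueError("merge_frame must fall inside the sequence")
    base = params or SceneParams()
    size_mm = base.image_size / base.px_per_mm
    mid = size_mm / 2.0
    offset = 32.0
    cell = replace(
        base, n_nodes=max(16, base.n_nodes // 2), cell_radius_mm=13.0,
        pseudopod_count=0,
    )
    rngs = [np.random.default_rng([seed, 77, i]) for i in range(3)]
    sides = []
    for s, sign in enumerate((-1, 1)):
        root_c = np.array([mid + sign * offset, mid])
        grow_c = np.array([mid + sign * (offset - 13.0), mid])
        rng = rngs[s]
        pts_a = _sample_points(rng, cell.n_nodes, root_c, 6.0, cell.min_node_sep_mm)
        pts_b = _sample_points(rng, cell.n_nodes, grow_c, cell.cell_radius_mm,
                               cell.min_node_sep_mm)
        pts = np.vstack([pts_a[: cell.n_nodes // 3], pts_b])
        g = _planar_graph(rng, pts, cell.hole_density, None)
        root = int(np.argmin(np.hypot(*(pts - root_c).T)))
        _assign_widths(rng, g, pts, root, cell)
        sides.append(dict(pts=pts, g=g, root=root, root_c=root_c))
    rng = rngs[2]
    # corridor endpoints: per side, n_corridors frontier nodes near the
    # mid-line with >= 5 mm vertical separation, matched in y-order
    ends = []
    for side in sides:
        pts = side["pts"]
        cand = list(np.argsort(np.abs(pts[:, 0] - mid)))[: max(8, 3 * n_corridors)]
        chosen: list[int] = []
        min_dy = 5.0
        while len(chosen) < n_corridors and min_dy > 1.0:
            chosen = []
            for i in cand:
                if all(abs(pts[i, 1] - pts[j, 1]) >= min_dy for j in chosen):
                    chosen.append(i)
                if len(chosen) == n_corridors:
                    break
            min_dy -= 1.0
        if len(chosen) < n_corridors:
            raise ValueError("cannot place that many separated corridors")
        chosen.sort(key=lambda i: pts[i, 1])
        ends.append(chosen)
    corridor_widths = [
        float(np.clip(fisk.rvs(cell.width_shape, scale=1.0, random_state=rng),
                      0.6, 1.6))
        for _ in range(n_corridors)
    ]
    valid = _valid_disc(base)
    dists = [
        nx.single_source_dijkstra_path_length(s["g"], s["root"], weight="length_mm")
        for s in sides
    ]
    # both cells reach full extent at merge_frame
    radii_per_side = []
    for d in dists:
        vals = np.sort(np.array(list(d.values())))
        qs = np.linspace(0.3, 1.0, merge_frame + 1)
        radii = [float(np.quantile(vals, q)) for q in qs]
        radii += [radii[-1]] * (n_frames - merge_frame - 1)
        radii_per_side.append(radii)
    scenes = []
    for t in range(n_frames):
        mask = np.zeros((base.image_size, base.image_size), dtype=bool)
        scale = np.ones_like(mask, dtype=float)
        init_mask = np.zeros_like(mask)
        edge_lists = []
        for s, side in enumerate(sides):
            r = radii_per_side[s][t]
            edges = [
                (u, v, d) for u, v, d in side["g"].edges(data=True)
                if dists[s][u] <= r and dists[s][v] <= r
            ]
            edge_lists.append(edges)
            for u, v, d in edges:
                _paint_segment(scale, mask, side["pts"][u], side["pts"][v],
                               d["width_mm"], base.px_per_mm,
                               _width_darkness(d["width_mm"], base))
            _paint_disc(scale, init_mask, side["root_c"],
                        base.initial_cell_radius_mm, base.px_per_mm, 0.72)
        mask |= init_mask
        corridor_edges = []
        if t >= merge_frame:
            shrink = 1.0
            if corridor_thinning > 0 and n_frames - 1 > merge_frame:
                frac = (t - merge_frame) / (n_frames - 1 - merge_frame)
                shrink = 1.0 - corridor_thinning * frac
            for k in range(n_corridors):
                i, j = ends[0][k], ends[1][k]
                p0, p1 = sides[0]["pts"][i], sides[1]["pts"][j]
                w = corridor_widths[k] * shrink
                # polyline with two mid-gap waypoints; short side stubs
                # make the waypoints true branch points, so the traced
                # graph has a mid-gap edge outside the max-flow boost zone
                j1 = np.array([mid - 3.0, p0[1]])
                j2 = np.array([mid + 3.0, p1[1]])
                dark = _width_darkness(w, base)
                for a, b in ((p0, j1), (j1, j2), (j2, p1)):
                    _paint_segment(scale, mask, a, b, w, base.px_per_mm, dark)
                stub_w = max(0.5, 0.55 * w)
                stub_dir = 1.0 if k % 2 == 0 else -1.0
                for jp, sgn in ((j1, stub_dir), (j2, -stub_dir)):
                    tip = jp + np.array([0.0, sgn * 2.0])
                    _paint_segment(scale, mask, jp, tip, stub_w, base.px_per_mm,
                                   _width_darkness(stub_w, base))
                corridor_edges.append((p0, p1, w))
        mask &= valid
        img = _render(mask, scale, valid, rng, base.noise_sd)
        # truth graph: union of both sides' included edges (+ corridors)
        tg = nx.Graph(px_per_mm=base.px_per_mm)
        for s, side in enumerate(sides):
            sub = _truth_graph_from(side["g"], side["pts"], base.px_per_mm,
                                    edge_lists[s])
            tg = nx.union(tg, sub, rename=(None, f"s{s}_"))
        scenes.append(SyntheticScene(
            frame=_frame_of(base, img, t * frame_interval_min),
            truth_mask=CellMask(foreground=mask, px_per_mm=base.px_per_mm),
            truth_graph=tg,
            pseudopod_mask=np.zeros_like(mask),
            initial_cell_mask=init_mask,
            params=base, seed=seed,
        ))
    truth = FusionTruth(
        merge_frame=merge_frame, n_corridors=n_corridors,
        corridor_widths_mm=corridor_widths,
        cell_centers_mm=(tuple(sides[0]["root_c"]), tuple(sides[1]["root_c"])),
    )
    return scenes, truth
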