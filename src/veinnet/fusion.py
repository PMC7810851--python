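"""Fusion of two slime-mold cells: fusion-time detection, fusion-region
delimitation, and post-fusion morphology / connectivity tracking.

When two expanding cells first touch, the newly grown material that
joins them defines the connecting set; the fusion region (FR) is the
slime within 5 mm of that set, offset outward by 2 mm.  Connectivity
between the two initial cells is quantified by max flow: with unit edge
capacities (boosted to 100 within 25 mm of each source node so the
bottleneck sits between the cells) the integer max flow counts the
edge-disjoint connecting veins; with width capacities it measures total
bandwidth, and bandwidth / count gives the mean connecting-vein width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage as ndi

from veinnet.imaging import CellMask
from veinnet.morphology import (
    morphological_indexes,
    skeletonize_with_width,
    skeleton_length_px,
)

_EIGHT = np.ones((3, 3), dtype=int)

BOOST_RADIUS_MM = 25.0
BOOST_CAPACITY = 100.0
FR_COLLAR_MM = 5.0
FR_OFFSET_MM = 2.0


class NoFusionError(RuntimeError):
    """Raised when the two cells never merge in the observed sequence."""


@dataclass(frozen=True)
class FusionRegion:
    """Fusion-region geometry derived from the before/after masks."""

    fusion_frame: int
    BF: np.ndarray
    AF: np.ndarray
    connecting_set: np.ndarray
    FR: np.ndarray
    px_per_mm: float


def _component_seeds(mask: np.ndarray, k: int | None = None) -> list[tuple[int, int]]:
    """One robust interior pixel (max distance transform) per component,
    ordered by decreasing component size; optionally only the ``k``
    largest components."""
    labels, n = ndi.label(mask, structure=_EIGHT)
    dist = ndi.distance_transform_edt(mask)
    sizes = np.bincount(labels.ravel())
    order = np.argsort(-sizes[1:]) + 1
    if k is not None:
        order = order[:k]
    seeds = []
    for i in order:
        comp = labels == i
        d = np.where(comp, dist, -1.0)
        seeds.append(np.unravel_index(np.argmax(d), d.shape))
    return seeds


def _two_cell_seeds(mask: np.ndarray, what: str) -> list[tuple[int, int]]:
    seeds = _component_seeds(mask)
    if len(seeds) < 2:
        raise ValueError(f"{what} must contain 2 cells, found {len(seeds)}")
    if len(seeds) > 2:
        warnings.warn(
            f"{what} has {len(seeds)} components; using the two largest as cells",
            stacklevel=3,
        )
    return seeds[:2]


def _joined(mask: np.ndarray, seeds: list[tuple[int, int]]) -> bool:
    labels, _ = ndi.label(mask, structure=_EIGHT)
    vals = {labels[s] for s in seeds}
    return 0 not in vals and len(vals) == 1


def detect_fusion_time(
    masks: list[np.ndarray] | list[CellMask], guess: int | None = None
) -> int:
    """Index of the earliest frame in which the two cells form one
    connected object.

    The two cells are seeded from the first frame's two components.
    With a ``guess``, the search walks outward from it in both
    directions; the result is still the earliest fused frame.
    """
    arrs = [m.foreground if isinstance(m, CellMask) else m for m in masks]
    seeds = _two_cell_seeds(arrs[0], "first frame")
    fused = lambda i: _joined(arrs[i], seeds)
    n = len(arrs)
    start = int(np.clip(guess, 0, n - 1)) if guess is not None else 0
    if guess is not None:
        if fused(start):
            i = start
            while i > 0 and fused(i - 1):
                i -= 1
            return i
        for i in range(start + 1, n):
            if fused(i):
                return i
        raise NoFusionError("cells never fuse in the sequence")
    for i in range(n):
        if fused(i):
            return i
    raise NoFusionError("cells never fuse in the sequence")


def _dilate_mm(mask: np.ndarray, radius_mm: float, ppm: float) -> np.ndarray:
    if radius_mm <= 0:
        return mask
    dist = ndi.distance_transform_edt(~mask)
    return dist <= radius_mm * ppm


def build_fusion_region(
    BF: np.ndarray, AF: np.ndarray, px_per_mm: float, fusion_frame: int = 0
) -> FusionRegion:
    """Delimit the fusion region from the mask right before fusion (BF,
    two cells) and the mask shortly after (AF, one object).

    New-growth components (AF minus BF) are added back to BF in
    decreasing-area order (ties broken by lexicographic centroid order)
    until the two cells connect; the added components form the
    connecting set.  FR is the slime of AF within 5 mm of the connecting
    set, dilated outward by 2 mm to capture adjacent expansion.
    """
    diff = AF & ~BF
    if not diff.any():
        raise ValueError("AF minus BF is empty; no new growth to connect")
    seeds = _two_cell_seeds(BF, "BF")
    labels, n = ndi.label(diff, structure=_EIGHT)
    comps = []
    for i in range(1, n + 1):
        comp = labels == i
        area = int(comp.sum())
        centroid = ndi.center_of_mass(comp)
        comps.append((-area, centroid, i, comp))
    comps.sort(key=lambda t: (t[0], t[1]))
    current = BF.copy()
    connecting = np.zeros_like(BF)
    joined = False
    for _, _, _, comp in comps:
        current |= comp
        connecting |= comp
        if _joined(current, seeds):
            joined = True
            break
    if not joined:
        raise NoFusionError("adding all new-growth regions never connects the cells")
    ppm = px_per_mm
    collar = ndi.distance_transform_edt(~connecting) <= FR_COLLAR_MM * ppm
    core = AF & collar
    fr = _dilate_mm(core | connecting, FR_OFFSET_MM, ppm)
    return FusionRegion(
        fusion_frame=fusion_frame, BF=BF, AF=AF,
        connecting_set=connecting, FR=fr, px_per_mm=ppm,
    )


def _nearest_node(g: nx.Graph, point_px: tuple[float, float]):
    best, best_d = None, np.inf
    for n, d in g.nodes(data=True):
        dd = (d["px"][0] - point_px[0]) ** 2 + (d["px"][1] - point_px[1]) ** 2
        if dd < best_d:
            best, best_d = n, dd
    return best


def source_nodes(g: nx.Graph, initial_mask: np.ndarray) -> tuple:
    """One graph node per initial cell: the node nearest the centroid of
    each of the two largest components of ``initial_mask`` (normally the
    first frame's two inoculation footprints)."""
    labels, n = ndi.label(initial_mask, structure=_EIGHT)
    if n < 2:
        raise ValueError(f"expected 2 initial cells, found {n}")
    sizes = np.bincount(labels.ravel())
    big = (np.argsort(-sizes[1:]) + 1)[:2]
    cents = ndi.center_of_mass(initial_mask, labels, list(big))
    s1 = _nearest_node(g, cents[0])
    s2 = _nearest_node(g, cents[1])
    if s1 == s2:
        raise ValueError("both cells map to the same graph node")
    return s1, s2


def _boosted_capacity(g: nx.Graph, src1, src2, base: str | None) -> nx.Graph:
    """Copy of g with flow capacities: base 1 (or edge width), boosted
    to 100 for edges touching the 25-mm zone around either source."""
    p1 = np.array(g.nodes[src1]["px"])
    p2 = np.array(g.nodes[src2]["px"])
    ppm = g.graph.get("px_per_mm", 1.0)
    r_px = BOOST_RADIUS_MM * ppm
    h = nx.Graph()
    h.add_nodes_from(g.nodes(data=True))
    for u, v, d in g.edges(data=True):
        cap = 1.0 if base is None else float(d["width_mm"])
        for node in (u, v):
            p = np.array(g.nodes[node]["px"])
            if np.hypot(*(p - p1)) <= r_px or np.hypot(*(p - p2)) <= r_px:
                cap = BOOST_CAPACITY
                break
        h.add_edge(u, v, capacity=cap)
    return h


def connecting_veins(g: nx.Graph, src1, src2) -> tuple[int, float]:
    """Count of edge-disjoint connecting veins between the two initial
    cells (unit-capacity max flow, boosted near the sources), and their
    average width (width-capacity bandwidth / count)."""
    if src1 == src2:
        raise ValueError("source nodes must differ")
    if not nx.has_path(g, src1, src2):
        warnings.warn("sources are disconnected; no connecting veins", stacklevel=2)
        return 0, 0.0
    unit = _boosted_capacity(g, src1, src2, base=None)
    n_connecting = int(round(nx.maximum_flow_value(unit, src1, src2)))
    widthcap = _boosted_capacity(g, src1, src2, base="width_mm")
    bandwidth = float(nx.maximum_flow_value(widthcap, src1, src2))
    avg_width = bandwidth / n_connecting if n_connecting else 0.0
    return n_connecting, avg_width


def intercell_paths(g: nx.Graph, src1, src2) -> tuple[float, float]:
    """Shortest inter-cell path length (mm) and minimum inter-cell drag."""
    if not nx.has_path(g, src1, src2):
        warnings.warn("sources are disconnected; infinite path values", stacklevel=2)
        return float("inf"), float("inf")
    plen = nx.dijkstra_path_length(g, src1, src2, weight="length_mm")
    pdrag = nx.dijkstra_path_length(g, src1, src2, weight="drag")
    return float(plen), float(pdrag)


def _mask_in_region(mask: np.ndarray, region: np.ndarray, ppm: float) -> CellMask:
    return CellMask(foreground=mask & region, px_per_mm=ppm)


def _node_in_region(g: nx.Graph, n, region: np.ndarray) -> bool:
    r = int(round(g.nodes[n]["px"][0]))
    c = int(round(g.nodes[n]["px"][1]))
    return (0 <= r < region.shape[0] and 0 <= c < region.shape[1]) and bool(region[r, c])


def fusion_timeseries(
    masks: list[np.ndarray],
    graphs: list[nx.Graph],
    region: FusionRegion,
    times_min: list[float] | None = None,
    initial_mask: np.ndarray | None = None,
) -> "pd.DataFrame":
    """Track the fusion-region indexes over the post-fusion frames.

    ``masks`` / ``graphs`` are the analysis frames (typically every
    15 min from fusion up to +180 min).  Morphological indexes are
    computed on mask ∩ FR; CA, PA, network length and max width are
    additionally reported normalized by their value at the first frame.
    Graph counts use FR membership of the node coordinates:
    ``edges_in_fr`` requires both endpoints inside, ``edges_across_fr``
    at least one.  Connectivity indexes (connecting veins, inter-cell
    paths) use the full graph with sources from the initial cells.
    """
    import pandas as pd

    ppm = region.px_per_mm
    if initial_mask is None:
        initial_mask = region.BF
    if times_min is None:
        times_min = [15.0 * i for i in range(len(masks))]
    rows = []
    for t, mask, g in zip(times_min, masks, graphs):
        sub = _mask_in_region(mask, region.FR, ppm)
        if not sub.foreground.any():
            warnings.warn(f"empty fusion-region mask at t={t}", stacklevel=2)
            continue
        mi = morphological_indexes(sub)
        skel = skeletonize_with_width(sub)
        length_fr = skeleton_length_px(skel.skeleton) / ppm
        on_skel = skel.half_width[skel.skeleton]
        mean_w = mi.CA / length_fr if length_fr > 0 else 0.0
        max_w = float(2.0 * on_skel.max()) if on_skel.size else 0.0
        in_fr = {n for n in g.nodes if _node_in_region(g, n, region.FR)}
        edges_in = sum(1 for u, v in g.edges() if u in in_fr and v in in_fr)
        edges_across = sum(1 for u, v in g.edges() if u in in_fr or v in in_fr)
        # connectivity on the main component: tiny segmentation
        # fragments must not capture a source node
        from veinnet.metrics import largest_component

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gc = largest_component(g)
        s1, s2 = source_nodes(gc, initial_mask)
        n_conn, avg_w = connecting_veins(gc, s1, s2)
        plen, pdrag = intercell_paths(gc, s1, s2)
        rows.append(dict(
            time_min=t, ca_fr=mi.CA, pa_fr=mi.PA,
            empty_ratio_fr=mi.empty_ratio, empty_mean_fr=mi.empty_mean,
            length_fr=length_fr, meanwidth_fr=mean_w, maxwidth_fr=max_w,
            nodes_in_fr=len(in_fr), edges_in_fr=edges_in,
            edges_across_fr=edges_across, n_connecting=n_conn,
            avg_connecting_width_mm=avg_w,
            path_length_mm=plen, path_drag=pdrag,
        ))
    df = pd.DataFrame(rows)
    if len(df):
        for col in ("ca_fr", "pa_fr", "length_fr", "maxwidth_fr"):
            base = df[col].iloc[0]
            df[f"{col}_norm"] = df[col] / base if base else np.nan
    return df
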