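"""End-to-end orchestration: frames -> masks -> graphs -> index tables.

The pre-fusion analysis samples the time-lapse at normalized covered
areas (multiples of the initial cell area, default 1.0 to 4.0 in steps
of 0.5, with the crossing times found by linear interpolation of the
time-area series) and emits one row of morphological and network
indexes per target.  The fusion analysis detects the fusion frame,
delimits the fusion region and tracks its indexes every 15 minutes for
three hours.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path

import imageio.v3 as iio
import networkx as nx
import numpy as np
import pandas as pd
import yaml

from veinnet.fusion import (
    NoFusionError,
    build_fusion_region,
    detect_fusion_time,
)
from veinnet.fusion import fusion_timeseries as _fusion_timeseries
from veinnet.graphs import classify_nodes, connectivity_indexes, extract_graph, simplify_graph
from veinnet.imaging import CellMask, Frame, SegmentationConfig, segment_frame
from veinnet.metrics import network_report
from veinnet.morphology import (
    morphological_indexes,
    pseudopod_regions,
    skeletonize_with_width,
)

logger = logging.getLogger("veinnet")

DEFAULT_AREA_TARGETS = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)


@dataclass
class RunConfig:
    """Configuration of a pipeline run (YAML-loadable)."""

    input_dir: str | None = None
    output_dir: str | None = None
    px_per_mm: float = 5.5
    dish_center_px: tuple[float, float] | None = None  # default: image centre
    dish_radius_mm: float = 45.0
    frame_interval_min: float = 1.0
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    area_targets: tuple[float, ...] = DEFAULT_AREA_TARGETS
    initial_area_mm2: float | None = None  # default: first frame's CA
    fusion_guess: int | None = None
    fusion_window_min: float = 180.0
    fusion_step_min: float = 15.0
    reps: int = 30
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        seg = SegmentationConfig(**raw.pop("segmentation", {}))
        targets = raw.pop("area_targets", None)
        cfg = cls(segmentation=seg, **raw)
        if targets is not None:
            cfg.area_targets = tuple(sorted(float(t) for t in targets))
        return cfg


def load_frames(input_dir: str | Path, config: RunConfig) -> list[Frame]:
    """Read a directory of photographs, ordered by filename."""
    paths = sorted(
        p for p in Path(input_dir).iterdir()
        if p.suffix.lower() in {".png", ".jpg", ".jpeg", ".tif", ".tiff"}
    )
    if not paths:
        raise FileNotFoundError(f"no image frames found in {input_dir}")
    frames = []
    for i, p in enumerate(paths):
        img = np.asarray(iio.imread(p))
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        img = img[..., :3].astype(np.uint8)
        center = config.dish_center_px or (
            (img.shape[0] - 1) / 2.0, (img.shape[1] - 1) / 2.0
        )
        frames.append(Frame(
            pixels=img, time_min=i * config.frame_interval_min,
            px_per_mm=config.px_per_mm, dish_center_px=center,
            dish_radius_px=config.dish_radius_mm * config.px_per_mm,
        ))
    return frames


def time_at_area(
    series: list[tuple[float, float]], an_target: float, initial_area: float
) -> float | None:
    """Time (min) at which the running-max normalized area first reaches
    ``an_target``, by linear interpolation; None when unreachable."""
    if initial_area <= 0:
        raise ValueError("initial_area must be positive")
    times = np.array([t for t, _ in series], dtype=float)
    areas = np.maximum.accumulate(np.array([a for _, a in series], dtype=float))
    an = areas / initial_area
    if an_target < an[0] or an_target > an[-1]:
        return None
    # earliest crossing: plateaus from the running max would otherwise
    # bias interpolation toward later frames
    i = int(np.argmax(an >= an_target))
    if an[i] == an_target or i == 0:
        return float(times[i])
    frac = (an_target - an[i - 1]) / (an[i] - an[i - 1])
    return float(times[i - 1] + frac * (times[i] - times[i - 1]))


def analyze_mask(
    mask: CellMask,
    initial_cell_mask: np.ndarray | None = None,
    reps: int = 30,
    rng_seed: int | None = None,
):
    """Mask -> (MorphIndexes, simplified VeinGraph, NetworkReport)."""
    pseudo, _ = pseudopod_regions(mask)
    morph = morphological_indexes(mask, pseudopod_mask=pseudo)
    skel = skeletonize_with_width(mask)
    g = simplify_graph(extract_graph(skel))
    classify_nodes(g, pseudopod_mask=pseudo, initial_cell_mask=initial_cell_mask)
    report = network_report(g, reps=reps, rng_seed=rng_seed)
    return morph, g, report


def _report_row(an: float, t_min: float, morph, report) -> dict:
    row = dict(
        normalized_area=an, time_min=t_min,
        CA_mm2=morph.CA, PA_mm2=morph.PA,
        empty_count=morph.empty_count, empty_total_mm2=morph.empty_total,
        empty_mean_mm2=morph.empty_mean, empty_ratio=morph.empty_ratio,
        pseudopod_fraction=morph.pseudopod_fraction,
        n_nodes=report.n_nodes, n_edges=report.n_edges,
        mean_degree=report.mean_degree, alpha=report.alpha,
        wiring_cost_length_mm=report.wiring_cost_length,
        wiring_cost_euclid_mm=report.wiring_cost_euclid,
        tortuosity=report.tortuosity, nnl=report.nnl, le=report.le,
        patheff_mean=report.patheff_mean, patheff_cov=report.patheff_cov,
        drageff_mean=report.drageff_mean, drageff_cov=report.drageff_cov,
        mu_bl=report.mu_bl, mu_bd=report.mu_bd,
    )
    for p, v in report.ft_raw.items():
        row[f"ft_raw_{p}"] = v
    for p, v in report.ft_norm.items():
        row[f"ft_norm_{p}"] = v
    return row


def export_graphml(g: nx.Graph, path: str | Path) -> None:
    """GraphML export; pixel tuples and pixel paths are not serializable
    and are dropped."""
    h = g.copy()
    for _, d in h.nodes(data=True):
        d.pop("px", None)
    for _, _, d in h.edges(data=True):
        d.pop("path", None)
    h.graph.pop("px_per_mm", None)
    nx.write_graphml(h, path)


def run_prefusion(
    config: RunConfig,
    frames: list[Frame] | None = None,
    masks: list[CellMask] | None = None,
) -> pd.DataFrame:
    """Per-normalized-area-target morphological and network index table.

    Frames are segmented (unless precomputed masks are given), the
    time-area series is accumulated over every frame, target crossing
    times come from linear interpolation (after a running max), and the
    frame nearest each crossing time is analyzed in full.
    """
    if masks is None:
        if frames is None:
            frames = load_frames(config.input_dir, config)
        masks = []
        times = []
        for fr in frames:
            try:
                masks.append(segment_frame(fr, config.segmentation))
                times.append(fr.time_min)
            except Exception as exc:  # pragma: no cover - defensive logging
                logger.warning("frame at t=%s failed (%s); skipped", fr.time_min, exc)
    else:
        times = [fr.time_min for fr in frames] if frames else [
            i * config.frame_interval_min for i in range(len(masks))
        ]
    if not masks:
        raise ValueError("no usable frames")
    cas = [m.area_mm2 for m in masks]
    series = list(zip(times, cas))
    initial_area = config.initial_area_mm2 or cas[0]
    initial_cell = masks[0].foreground.copy()
    # the initial-cell footprint is the first mask dilated by 0.5 mm
    from scipy import ndimage as ndi

    dil = ndi.distance_transform_edt(~initial_cell) <= 0.5 * config.px_per_mm
    initial_cell = initial_cell | dil
    rows = []
    t_arr = np.asarray(times)
    for i, an in enumerate(config.area_targets):
        t = time_at_area(series, an, initial_area)
        if t is None:
            logger.warning("normalized area %.2f unreachable; skipped", an)
            continue
        k = int(np.argmin(np.abs(t_arr - t)))
        morph, g, report = analyze_mask(
            masks[k], initial_cell_mask=initial_cell,
            reps=config.reps, rng_seed=config.seed + i,
        )
        rows.append(_report_row(an, t, morph, report))
        if config.output_dir:
            export_graphml(g, Path(config.output_dir) / f"graph_an{an:.1f}.graphml")
    df = pd.DataFrame(rows)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "indexes.csv", index=False)
    return df


def run_fusion(
    config: RunConfig,
    frames: list[Frame] | None = None,
    masks: list[CellMask] | None = None,
) -> pd.DataFrame:
    """Fusion-region index table: 13 rows (0..180 min, step 15) unless
    the sequence ends earlier (then truncated with a warning)."""
    if masks is None:
        if frames is None:
            frames = load_frames(config.input_dir, config)
        masks = [segment_frame(fr, config.segmentation) for fr in frames]
    arrs = [m.foreground for m in masks]
    ppm = masks[0].px_per_mm
    fusion_frame = detect_fusion_time(arrs, guess=config.fusion_guess)
    bf_idx = max(0, fusion_frame - 1)
    af_off = max(1, ceil(5.0 / config.frame_interval_min))
    af_idx = min(len(arrs) - 1, fusion_frame + af_off)
    region = build_fusion_region(
        arrs[bf_idx], arrs[af_idx], ppm, fusion_frame=fusion_frame
    )
    step_frames = max(1, int(round(config.fusion_step_min / config.frame_interval_min)))
    n_steps = int(config.fusion_window_min // config.fusion_step_min) + 1
    sel = [fusion_frame + i * step_frames for i in range(n_steps)]
    in_range = [i for i in sel if i < len(arrs)]
    if len(in_range) < len(sel):
        warnings.warn(
            f"sequence ends before +{config.fusion_window_min:.0f} min; "
            f"series truncated to {len(in_range)} steps", stacklevel=2,
        )
    sub_masks = [arrs[i] for i in in_range]
    graphs = []
    for i in in_range:
        skel = skeletonize_with_width(masks[i])
        graphs.append(simplify_graph(extract_graph(skel)))
    t0 = in_range[0]
    times = [(i - t0) * config.frame_interval_min for i in in_range]
    df = _fusion_timeseries(sub_masks, graphs, region, times_min=times,
                            initial_mask=arrs[0])
    df.insert(0, "fusion_frame", fusion_frame)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "fusion_series.csv", index=False)
    return df
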