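"""Morphological indexes of a segmented cell: areas, holes, skeleton,
vein widths and pseudopods.

Covered area (CA) counts cell pixels; print area (PA) additionally
includes the enclosed empty regions ("holes") inside the cell contour.
The topological skeleton (Lee thinning) together with the Euclidean
distance transform yields vein half-widths, and a step-weighted trace of
the skeleton yields the total network length.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk, opening, skeletonize

from veinnet.imaging import CellMask

_EIGHT = np.ones((3, 3), dtype=int)
_FOUR = ndi.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class MorphIndexes:
    """Per-frame morphological index vector (areas in mm^2)."""

    CA: float
    PA: float
    empty_count: int
    empty_total: float
    empty_mean: float
    empty_ratio: float
    pseudopod_fraction: float = 0.0


@dataclass(frozen=True)
class SkeletonField:
    """Medial axis of the cell and per-pixel half vein width.

    ``half_width`` holds, on skeleton pixels, the Euclidean distance (mm)
    to the nearest background pixel; the vein width is twice that.
    """

    skeleton: np.ndarray
    half_width: np.ndarray
    px_per_mm: float


def morphological_indexes(
    mask: CellMask, pseudopod_mask: np.ndarray | None = None
) -> MorphIndexes:
    """Covered/print areas and enclosed-empty-region statistics.

    Holes are 4-connected background regions fully enclosed by the cell;
    PA = CA + total hole area.
    """
    fg = mask.foreground
    if not fg.any():
        raise ValueError("empty mask")
    ppm2 = mask.px_per_mm**2
    ca = float(fg.sum()) / ppm2
    filled = ndi.binary_fill_holes(fg, structure=_FOUR)
    holes = filled & ~fg
    _, n_holes = ndi.label(holes, structure=_FOUR)
    empty_total = float(holes.sum()) / ppm2
    pa = ca + empty_total
    empty_mean = empty_total / n_holes if n_holes else 0.0
    empty_ratio = empty_total / ca
    frac = 0.0
    if pseudopod_mask is not None:
        frac = float((pseudopod_mask & fg).sum()) / float(fg.sum())
    return MorphIndexes(
        CA=ca,
        PA=pa,
        empty_count=int(n_holes),
        empty_total=empty_total,
        empty_mean=empty_mean,
        empty_ratio=empty_ratio,
        pseudopod_fraction=frac,
    )


def skeletonize_with_width(mask: CellMask) -> SkeletonField:
    """Lee-thinning skeleton with the exact Euclidean half-width.

    The distance transform from the cell boundary, sampled on the medial
    axis, is half the local vein width.
    """
    fg = mask.foreground
    if not fg.any():
        raise ValueError("empty mask")
    skel = skeletonize(fg, method="lee").astype(bool)
    dist_px = ndi.distance_transform_edt(fg)
    half_width = np.where(skel, dist_px / mask.px_per_mm, 0.0)
    return SkeletonField(skeleton=skel, half_width=half_width, px_per_mm=mask.px_per_mm)


def skeleton_length_px(skeleton: np.ndarray) -> float:
    """Step-weighted skeleton length in pixel units.

    Orthogonally adjacent pixel pairs contribute 1, diagonal pairs
    sqrt(2).  A diagonal adjacency whose two pixels share a 4-neighbour
    on the skeleton is redundant (the path already runs through the
    shared pixel) and is not counted.
    """
    s = skeleton.astype(bool)
    # orthogonal pairs
    n_ortho = int((s[:-1, :] & s[1:, :]).sum() + (s[:, :-1] & s[:, 1:]).sum())
    # diagonal pairs, dropping those short-circuiting a common 4-neighbour
    d1 = s[:-1, :-1] & s[1:, 1:]  # (r,c)-(r+1,c+1)
    d1_red = d1 & (s[:-1, 1:] | s[1:, :-1])
    d2 = s[:-1, 1:] & s[1:, :-1]  # (r,c+1)-(r+1,c)
    d2_red = d2 & (s[:-1, :-1] | s[1:, 1:])
    n_diag = int((d1 & ~d1_red).sum() + (d2 & ~d2_red).sum())
    return n_ortho + sqrt(2.0) * n_diag


def network_length_and_mean_width(
    skel: SkeletonField, CA: float
) -> tuple[float, float]:
    """Total skeleton length (mm) and mean vein width CA / length (mm).

    By construction ``mean_width * total_length == CA`` exactly.
    """
    if not skel.skeleton.any():
        raise ValueError("empty skeleton")
    total_px = skeleton_length_px(skel.skeleton)
    if total_px <= 0:
        raise ValueError("zero-length skeleton")
    total_length = total_px / skel.px_per_mm
    return total_length, CA / total_length


def pseudopod_regions(
    mask: CellMask, radius_mm: float = 1.0
) -> tuple[np.ndarray, float]:
    """Pseudopod mask by morphological opening with a disc of
    ``radius_mm``, and the pseudopod area fraction.

    Thin veins vanish under the opening; the thick fan-like frontier
    regions that survive are labelled pseudopods.
    """
    fg = mask.foreground
    r_px = max(1, int(round(radius_mm * mask.px_per_mm)))
    opened = opening(fg, disk(r_px))
    total = float(fg.sum())
    frac = float(opened.sum()) / total if total else 0.0
    return opened, frac
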