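"""Segmentation of slime-mold cells from calibrated dish photographs.

The cell body (light yellow) is barely separable from the pale agar
background in RGB, so segmentation works in CIELAB: the scalar intensity
``L - b`` is low for yellow cell pixels and high for the background.
That intensity field is binarized with Bradley's adaptive dark-foreground
threshold, and thin fading veins that the threshold misses are recovered
by watershed ridge detection on the blurred field.  The union of the two
masks is the final segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2lab
from skimage.morphology import h_minima
from skimage.segmentation import watershed


class ConfigurationError(ValueError):
    """Raised when dish geometry or segmentation parameters are invalid."""


@dataclass(frozen=True)
class Frame:
    """One calibrated RGB photograph of the dish.

    Parameters
    ----------
    pixels : ndarray, shape (rows, cols, 3), uint8
        The photograph.
    time_min : float
        Minutes since the start of the experiment.
    px_per_mm : float
        Pixel pitch of the calibrated image (> 0).
    dish_center_px : tuple of float
        (row, col) of the dish centre, in pixels.
    dish_radius_px : float
        Dish radius in pixels.
    """

    pixels: np.ndarray
    time_min: float
    px_per_mm: float
    dish_center_px: tuple[float, float]
    dish_radius_px: float

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ConfigurationError("pixels must be an RGB raster (rows, cols, 3)")
        if self.px_per_mm <= 0:
            raise ConfigurationError("px_per_mm must be positive")
        if self.time_min < 0:
            raise ConfigurationError("time_min must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class IntensityField:
    """Normalized scalar intensity field with an in-dish validity mask.

    ``values`` lie in [0, 1] over the valid pixels (min-max normalized;
    all zero if the field is constant).  Cell pixels are LOW, matching
    the dark-foreground binarization convention.
    """

    values: np.ndarray
    valid_mask: np.ndarray
    px_per_mm: float


@dataclass(frozen=True)
class CellMask:
    """Binary segmentation of the cell, with calibration carried along."""

    foreground: np.ndarray
    px_per_mm: float

    @property
    def area_mm2(self) -> float:
        return float(self.foreground.sum()) / self.px_per_mm**2


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable parameters of the segmentation stages.

    ``window_mm`` defaults to one eighth of the dish diameter when left
    as None.  ``sensitivity`` is Bradley's discount on the local mean: a
    pixel is foreground when its value falls below
    ``(1 - sensitivity) * local_mean``.
    """

    laplacian_gain: float = 1.0
    laplacian_presmooth_sigma: float = 1.0
    window_mm: float | None = None
    sensitivity: float = 0.10
    min_contrast: float = 0.10
    min_range: float = 30.0
    sigma_px: float = 2.0
    ridge_depth: float = 0.02
    min_component_mm2: float = 0.05
    rim_margin_px: float = 0.0


# 3x3 four-neighbour Laplacian.
_LAPLACIAN = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


def mask_dish(frame: Frame, rim_margin_px: float = 0.0) -> np.ndarray:
    """Boolean raster of pixels inside the dish (minus a rim margin).

    Pixel centres within ``dish_radius_px - rim_margin_px`` of the dish
    centre are valid.  The dish circle must fit inside the raster.
    """
    rows, cols = frame.shape
    cr, cc = frame.dish_center_px
    radius = frame.dish_radius_px
    if radius < 0:
        raise ConfigurationError("dish radius must be non-negative")
    if radius > 0 and (
        cr - radius < -0.5
        or cc - radius < -0.5
        or cr + radius > rows - 0.5
        or cc + radius > cols - 0.5
    ):
        raise ConfigurationError("dish circle exceeds raster bounds")
    eff = radius - rim_margin_px
    if eff <= 0:
        return np.zeros((rows, cols), dtype=bool)
    rr, cc_grid = np.ogrid[:rows, :cols]
    return (rr - cr) ** 2 + (cc_grid - cc) ** 2 <= eff**2


def enhance_contrast(frame: Frame, k: float = 1.0, presmooth_sigma: float = 1.0) -> Frame:
    """Unsharp-mask the photograph with a four-neighbour Laplacian.

    output = input - k * Laplacian(input), per channel, clipped to 8 bits.
    With ``presmooth_sigma`` > 0 the Laplacian is taken of a Gaussian-
    smoothed copy (a Laplacian-of-Gaussian), which sharpens structure
    without amplifying per-pixel sensor noise; ``presmooth_sigma = 0``
    gives the raw 3x3 convolution.
    """
    img = frame.pixels.astype(np.float64)
    out = np.empty_like(img)
    for ch in range(3):
        base = img[..., ch]
        if presmooth_sigma > 0:
            base = ndi.gaussian_filter(base, presmooth_sigma)
        lap = ndi.convolve(base, _LAPLACIAN, mode="nearest")
        out[..., ch] = img[..., ch] - k * lap
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return Frame(
        pixels=out,
        time_min=frame.time_min,
        px_per_mm=frame.px_per_mm,
        dish_center_px=frame.dish_center_px,
        dish_radius_px=frame.dish_radius_px,
    )


def compute_intensity(
    frame: Frame, valid_mask: np.ndarray, min_range: float = 15.0
) -> IntensityField:
    """CIELAB ``L - b`` intensity, min-max normalized to [0, 1] in-dish.

    Yellow cell pixels (high b) map to low values and pale background to
    high values, so the cell is the *dark* foreground.  A constant field
    normalizes to all zeros; so does a nearly constant one — robust raw
    ``L - b`` spread (1st to 99th percentile) below ``min_range`` L
    units and no pixel more than ``2 * min_range`` from any other —
    because stretching the sensor noise of a cell-free dish over [0, 1]
    would manufacture contrast out of nothing, while a genuine if tiny
    foreground still shows a large full range.  Uses the D65 illuminant,
    2-degree observer.
    """
    if not valid_mask.any():
        raise ConfigurationError("valid_mask is empty")
    lab = rgb2lab(frame.pixels)
    raw = lab[..., 0] - lab[..., 2]
    lo = raw[valid_mask].min()
    hi = raw[valid_mask].max()
    robust = float(
        np.quantile(raw[valid_mask], 0.99) - np.quantile(raw[valid_mask], 0.01)
    )
    if hi - lo <= 0 or (robust < min_range and hi - lo < 2 * min_range):
        values = np.zeros_like(raw)
    else:
        values = (raw - lo) / (hi - lo)
        values = np.clip(values, 0.0, 1.0)
    values = np.where(valid_mask, values, 0.0)
    return IntensityField(values=values, valid_mask=valid_mask, px_per_mm=frame.px_per_mm)


def _remove_small(mask: np.ndarray, min_px: float) -> np.ndarray:
    """Drop 8-connected components smaller than ``min_px`` pixels."""
    if min_px <= 1 or not mask.any():
        return mask
    labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[labels]


def binarize_adaptive(
    field: IntensityField,
    window_mm: float,
    sensitivity: float = 0.10,
    min_component_mm2: float = 0.05,
    min_contrast: float = 0.10,
) -> CellMask:
    """Bradley adaptive threshold for dark foregrounds.

    A pixel is foreground iff its value is below ``(1 - sensitivity)``
    times the mean over a square window of side ``window_mm`` (converted
    to pixels) AND sits at least ``min_contrast`` below that mean — the
    absolute floor keeps flat regions (where a fraction of the relative
    margin is within the noise) out of the mask, which is what makes a
    contrast-inverted field come back empty.  Components smaller than
    ``min_component_mm2`` are removed.
    """
    win_px = int(round(window_mm * field.px_per_mm))
    if win_px < 3:
        raise ConfigurationError("adaptive window must be at least 3 px")
    # Local mean over in-dish pixels only, so the rim does not bias it.
    valid = field.valid_mask
    vals = np.where(valid, field.values, 0.0)
    kernel_sum = ndi.uniform_filter(vals, size=win_px, mode="constant") * win_px**2
    kernel_cnt = ndi.uniform_filter(valid.astype(float), size=win_px, mode="constant") * win_px**2
    with np.errstate(invalid="ignore", divide="ignore"):
        local_mean = np.where(kernel_cnt > 0, kernel_sum / kernel_cnt, 0.0)
    fg = (
        valid
        & (field.values < (1.0 - sensitivity) * local_mean)
        & (local_mean - field.values >= min_contrast)
    )
    fg = _remove_small(fg, min_component_mm2 * field.px_per_mm**2)
    return CellMask(foreground=fg, px_per_mm=field.px_per_mm)


def detect_ridges(
    field: IntensityField, sigma_px: float = 2.0, depth: float = 0.02
) -> np.ndarray:
    """Watershed centrelines of dark veins, as 1-px-wide boundary lines.

    The field is Gaussian-blurred, negated (veins become crests) and
    flooded from its h-minima (markers deeper than ``depth``); the
    watershed boundary lines between catchment basins trace the vein
    centrelines.  Returns a boolean raster restricted to the valid mask.
    """
    blurred = ndi.gaussian_filter(field.values, sigma=sigma_px)
    neg = -blurred
    minima = h_minima(neg, depth)
    markers, n_markers = ndi.label(minima, structure=np.ones((3, 3), dtype=int))
    if n_markers < 2:
        return np.zeros_like(field.valid_mask)
    labels = watershed(neg, markers=markers, watershed_line=True)
    return (labels == 0) & field.valid_mask


def segment_frame(frame: Frame, config: SegmentationConfig | None = None) -> CellMask:
    """Full segmentation: mask dish, enhance, L-b intensity, threshold
    union ridge lines, drop small components.

    Deterministic for fixed (frame, config).
    """
    cfg = config or SegmentationConfig()
    valid = mask_dish(frame, rim_margin_px=cfg.rim_margin_px)
    enhanced = enhance_contrast(
        frame, k=cfg.laplacian_gain, presmooth_sigma=cfg.laplacian_presmooth_sigma
    )
    field = compute_intensity(enhanced, valid, min_range=cfg.min_range)
    window_mm = cfg.window_mm
    if window_mm is None:
        window_mm = 2.0 * frame.dish_radius_px / frame.px_per_mm / 8.0
    adaptive = binarize_adaptive(
        field, window_mm, cfg.sensitivity, cfg.min_component_mm2,
        min_contrast=cfg.min_contrast,
    )
    ridges = detect_ridges(field, sigma_px=cfg.sigma_px, depth=cfg.ridge_depth)
    union = adaptive.foreground | ridges
    union = _remove_small(union, cfg.min_component_mm2 * frame.px_per_mm**2)
    return CellMask(foreground=union, px_per_mm=frame.px_per_mm)
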