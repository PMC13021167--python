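"""Deterministic image conditioning: rolling-ball background subtraction,
CLAHE, tissue masking, z-normalization, physical-size cropping and
nearest-neighbor resizing.

The rolling-ball step is implemented as grayscale opening with a sliding
paraboloid z(d) = d^2 / (2 r), the curvature a ball of the given radius has
at its apex.  The paraboloid is separable (d^2 = dx^2 + dy^2), so the
erosion/dilation pair runs as two 1-D passes per axis, which makes the
50-pixel default radius tractable on full planes.  Fluorescence images are
dark-background, so the opening is applied directly (no inversion).
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage.exposure import equalize_adapthist
from skimage.transform import resize as _sk_resize

from .errors import DegenerateInputError
from .raster_io import Box, ImagePlane, RGBImage
from .virtual_stain import multi_otsu, to_grayscale

DEFAULT_ROLLING_BALL_RADIUS = 50        # px
DEFAULT_CROP_EDGE_UM = 245.52           # physical crop edge
DEFAULT_CLAHE_CLIP = 0.01
DEFAULT_CLAHE_GRID = (8, 8)


# ---------------------------------------------------------------------------
# Rolling-ball background subtraction
# ---------------------------------------------------------------------------

def _paraboloid_pass_1d(x: np.ndarray, curv: float, support: int, axis: int, op) -> np.ndarray:
    """One 1-D erosion/dilation with the separable paraboloid profile."""
    pad_val = np.inf if op is np.minimum else -np.inf
    m = support
    x = np.moveaxis(x, axis, -1)
    padded = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(m, m)], constant_values=pad_val)
    acc = np.full_like(x, pad_val, dtype=float)
    n = x.shape[-1]
    for d in range(-m, m + 1):
        shifted = padded[..., m + d : m + d + n]
        offset = curv * d * d
        acc = op(acc, shifted + offset if op is np.minimum else shifted - offset)
    return np.moveaxis(acc, -1, axis)


def rolling_ball_subtract(plane: ImagePlane, radius_px: int = DEFAULT_ROLLING_BALL_RADIUS) -> ImagePlane:
    """Estimate background by paraboloid opening and subtract it (clip at 0)."""
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    rows, cols = plane.shape
    if radius_px > rows and radius_px > cols:
        raise ValueError(f"radius {radius_px} exceeds both image dimensions {plane.shape}")
    data = np.asarray(plane.data, dtype=float)
    vrange = float(data.max() - data.min())
    if vrange == 0.0:
        return ImagePlane(np.zeros_like(data), plane.bit_depth, plane.pixel_pitch_um)
    curv = 1.0 / (2.0 * radius_px)
    # paraboloid support: beyond this offset its depth exceeds the dynamic range
    support = int(np.ceil(np.sqrt(vrange / curv)))
    support = min(support, max(rows, cols))
    eroded = data
    for axis in (0, 1):
        eroded = _paraboloid_pass_1d(eroded, curv, support, axis, np.minimum)
    background = eroded
    for axis in (0, 1):
        background = _paraboloid_pass_1d(background, curv, support, axis, np.maximum)
    out = np.clip(data - background, 0.0, None)
    return ImagePlane(out, plane.bit_depth, plane.pixel_pitch_um)


# ---------------------------------------------------------------------------
# CLAHE
# ---------------------------------------------------------------------------

def clahe(
    plane,
    clip_limit: float = DEFAULT_CLAHE_CLIP,
    tile_grid: tuple[int, int] = DEFAULT_CLAHE_GRID,
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization; output float [0,1].

    Accepts an :class:`ImagePlane` (scaled by its bit range) or a raw array
    (scaled by its own extrema).  Constant input maps to constant zeros.
    """
    if isinstance(plane, ImagePlane):
        data = np.asarray(plane.data, dtype=float) / plane.max_value
    else:
        data = np.asarray(plane, dtype=float)
        rng = data.max() - data.min()
        data = (data - data.min()) / rng if rng > 0 else data * 0.0
    if data.size == 0:
        raise ValueError("empty plane")
    if data.max() == data.min():
        return np.zeros_like(data, dtype=float)
    kernel = (
        max(1, data.shape[0] // tile_grid[0]),
        max(1, data.shape[1] // tile_grid[1]),
    )
    return equalize_adapthist(np.clip(data, 0.0, 1.0), kernel_size=kernel, clip_limit=clip_limit)


# ---------------------------------------------------------------------------
# Tissue mask and normalization
# ---------------------------------------------------------------------------

def tissue_mask(he: RGBImage) -> np.ndarray:
    """Tissue = pixels strictly below the HIGH of two multi-Otsu thresholds
    of the grayscale image (glass/background is the brightest mode)."""
    gray = to_grayscale(he.data)
    try:
        _, t_high = multi_otsu(gray, n_classes=3, n_bins=255)
    except DegenerateInputError:
        warnings.warn("constant image; empty tissue mask")
        return np.zeros(gray.shape, dtype=np.uint8)
    return (gray < t_high).astype(np.uint8)


def znorm(x) -> np.ndarray:
    """(x - mean) / std over the whole plane; constant input -> zeros."""
    data = np.asarray(x.data if isinstance(x, ImagePlane) else x, dtype=float)
    sd = float(data.std())
    if sd == 0.0:
        warnings.warn("zero-variance input; z-normalization returns zeros")
        return np.zeros_like(data)
    return (data - data.mean()) / sd


# ---------------------------------------------------------------------------
# Cropping and resizing
# ---------------------------------------------------------------------------

def crop_edge_px(pixel_pitch_um: float, crop_edge_um: float = DEFAULT_CROP_EDGE_UM) -> int:
    """Physical crop edge in pixels, rounded half away from zero."""
    if pixel_pitch_um <= 0 or crop_edge_um <= 0:
        raise ValueError("pixel pitch and crop edge must be positive")
    return int(np.floor(crop_edge_um / pixel_pitch_um + 0.5))


def crop_boxes(
    shape: tuple[int, int],
    pixel_pitch_um: float,
    crop_edge_um: float = DEFAULT_CROP_EDGE_UM,
) -> list[Box]:
    """Regular grid of half-open square boxes anchored at (0,0); partial
    tiles at the right/bottom edges are discarded."""
    edge = crop_edge_px(pixel_pitch_um, crop_edge_um)
    if edge < 1:
        raise ValueError("crop edge rounds to less than one pixel")
    rows, cols = shape
    boxes: list[Box] = []
    for r0 in range(0, rows - edge + 1, edge):
        for c0 in range(0, cols - edge + 1, edge):
            boxes.append((r0, r0 + edge, c0, c0 + edge))
    return boxes


def resize(raster: np.ndarray, target_shape: tuple[int, int], method: str = "nearest") -> np.ndarray:
    """Nearest-neighbor resampling; label rasters keep their value set."""
    if method != "nearest":
        raise ValueError("only nearest-neighbor resizing is supported here")
    if target_shape[0] < 1 or target_shape[1] < 1:
        raise ValueError("target dimensions must be >= 1")
    raster = np.asarray(raster)
    if raster.shape[:2] == tuple(target_shape):
        return raster.copy()
    out_shape = tuple(target_shape) + raster.shape[2:]
    out = _sk_resize(
        raster, out_shape, order=0, preserve_range=True, anti_aliasing=False, mode="edge"
    )
    return out.astype(raster.dtype)
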