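"""Bidirectional virtual staining between brightfield H&E and two-channel
DRAQ5&Eosin fluorescence.

Forward direction (H&E -> synthetic D&E) is the transfer-learning recipe
used to pre-train on public H&E archives: a nuclei mask from multi-Otsu
thresholding splits the image into a nuclear (DRAQ5-like) and a
cytoplasmic (Eosin-like) channel, each inverted, lightly noised, dilated,
smoothed, rescaled to 12 bits and z-normalized.

Reverse direction (D&E -> synthetic H&E) is Beer-Lambert recoloring: each
fluorescence channel, normalized to [0,1] and gamma-compressed with
gamma > 1, acts as the concentration of a virtual stain whose RGB optical
densities follow conventional hematoxylin/eosin absorption directions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.morphology import dilation, disk, erosion

from .errors import DegenerateInputError
from .raster_io import DEImage, ImagePlane, RGBImage

#: Standard luma weights for RGB -> grayscale conversion.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Conventional H&E optical-density directions, scaled so the strongest
#: channel absorbs with unit optical density.
OD_HEMATOXYLIN_RGB = np.array([0.65, 0.70, 0.29]) / 0.70
OD_EOSIN_RGB = np.array([0.07, 0.99, 0.11]) / 0.99


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """Luma grayscale on the 0..255 scale."""
    return np.asarray(rgb, dtype=float) @ LUMA_WEIGHTS


@dataclass
class SyntheticDEParams:
    noise_variance: float = 0.0001
    smoothing_sigma: float = 0.5
    scale_max: int = 4095
    erosion_radius_px: int = 1
    dilation_radius_px: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_variance < 0 or self.smoothing_sigma < 0:
            raise ValueError("noise_variance and smoothing_sigma must be >= 0")


@dataclass
class SyntheticHEParams:
    gamma_draq5: float = 1.5
    gamma_eosin: float = 1.5
    od_hematoxylin_rgb: np.ndarray = field(default_factory=lambda: OD_HEMATOXYLIN_RGB.copy())
    od_eosin_rgb: np.ndarray = field(default_factory=lambda: OD_EOSIN_RGB.copy())
    background_level: int = 255

    def __post_init__(self) -> None:
        if not (self.gamma_draq5 > 1 and self.gamma_eosin > 1):
            raise ValueError("gamma factors must be > 1")
        self.od_hematoxylin_rgb = np.asarray(self.od_hematoxylin_rgb, dtype=float)
        self.od_eosin_rgb = np.asarray(self.od_eosin_rgb, dtype=float)
        if (self.od_hematoxylin_rgb < 0).any() or (self.od_eosin_rgb < 0).any():
            raise ValueError("optical-density vectors must be non-negative")


# ---------------------------------------------------------------------------
# Multi-Otsu thresholding
# ---------------------------------------------------------------------------

def _segment_score_matrix(counts: np.ndarray, values: np.ndarray) -> np.ndarray:
    """score[a, b] = S^2/W of bins a..b inclusive (0 for zero-weight runs).

    Maximizing the sum of S^2/W over classes is equivalent to maximizing
    between-class variance for a fixed histogram.
    """
    cw = np.concatenate([[0.0], np.cumsum(counts)])
    cs = np.concatenate([[0.0], np.cumsum(counts * values)])
    w = cw[None, 1:] - cw[:-1, None]  # w[a, b] over a <= b
    s = cs[None, 1:] - cs[:-1, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(w > 0, s * s / np.where(w > 0, w, 1.0), 0.0)
    return score


def _optimal_cuts(counts: np.ndarray, values: np.ndarray, n_classes: int) -> list[int]:
    """Exact dynamic program over cut positions maximizing between-class
    variance; ties resolved toward the smallest cut indices."""
    b = counts.size
    score = _segment_score_matrix(counts, values)
    # best[k-1][t] = best objective for bins 0..t split into k classes
    best = np.full((n_classes, b), -np.inf)
    arg = np.zeros((n_classes, b), dtype=int)
    best[0] = score[0]
    for k in range(1, n_classes):
        # class k starts at cut c (k <= c <= t), previous classes cover 0..c-1
        for t in range(k, b):
            cand = best[k - 1, k - 1 : t] + score[k : t + 1, t]
            j = int(np.argmax(cand))
            best[k, t] = cand[j]
            arg[k, t] = j + k
    cuts = []
    t = b - 1
    for k in range(n_classes - 1, 0, -1):
        c = arg[k, t]
        cuts.append(int(c))
        t = c - 1
    return cuts[::-1]


def multi_otsu(plane_or_histogram, n_classes: int = 3, n_bins: int = 255):
    """Thresholds maximizing between-class variance on a binned histogram.

    Accepts either an intensity raster/:class:`ImagePlane` (binned into
    ``n_bins`` equal-width bins over its value range; thresholds returned on
    the intensity scale) or a 1-D histogram of counts over integer values
    0..len-1 (thresholds returned as integer cut values: class k contains
    values strictly below threshold k).
    """
    if not 2 <= n_classes <= 5:
        raise ValueError("n_classes must be in 2..5")
    if n_bins < n_classes:
        raise ValueError("n_bins must be >= n_classes")

    if isinstance(plane_or_histogram, ImagePlane):
        data = np.asarray(plane_or_histogram.data, dtype=float)
    else:
        data = np.asarray(plane_or_histogram, dtype=float)

    if data.ndim == 1:  # histogram input
        counts = data
        values = np.arange(counts.size, dtype=float)
        if np.count_nonzero(counts) < n_classes:
            raise DegenerateInputError("histogram has fewer occupied bins than classes")
        cuts = _optimal_cuts(counts, values, n_classes)
        return [float(c) for c in cuts]

    vmin, vmax = float(data.min()), float(data.max())
    if vmin == vmax:
        raise DegenerateInputError("constant image has no thresholds")
    edges = np.linspace(vmin, vmax, n_bins + 1)
    counts, _ = np.histogram(data, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    cuts = _optimal_cuts(counts.astype(float), centers, n_classes)
    return [float(edges[c]) for c in cuts]


# ---------------------------------------------------------------------------
# H&E -> synthetic D&E
# ---------------------------------------------------------------------------

def nuclei_mask_from_he(he: RGBImage, erosion_radius_px: int = 1) -> np.ndarray:
    """Binary nuclei mask: pixels strictly below the lower of two multi-Otsu
    thresholds of the grayscale image, then eroded by a small disk."""
    gray = to_grayscale(he.data)
    try:
        t_low, _ = multi_otsu(gray, n_classes=3, n_bins=255)
    except DegenerateInputError:
        warnings.warn("constant H&E image; empty nuclei mask")
        return np.zeros(gray.shape, dtype=np.uint8)
    mask = gray < t_low
    if erosion_radius_px > 0:
        mask = erosion(mask, disk(erosion_radius_px))
    return mask.astype(np.uint8)


def _invert_preserving_zero(gray: np.ndarray) -> np.ndarray:
    """Map brightest <-> darkest on [0,1] while keeping exact zeros at zero
    (zeros mark masked-out background, not true intensity)."""
    return np.where(gray > 0, (255.0 - gray) / 255.0, 0.0)


def _de_channel_chain(
    inv: np.ndarray, params: SyntheticDEParams, rng: np.random.Generator
) -> np.ndarray:
    if params.noise_variance > 0:
        inv = inv + rng.normal(0.0, np.sqrt(params.noise_variance), inv.shape)
    if params.dilation_radius_px > 0:
        inv = dilation(inv, disk(params.dilation_radius_px))
    if params.smoothing_sigma > 0:
        inv = gaussian_filter(inv, params.smoothing_sigma)
    return np.clip(inv, 0.0, 1.0) * params.scale_max


def _znorm_plane(x: np.ndarray) -> np.ndarray:
    sd = float(x.std())
    if sd == 0.0:
        warnings.warn("zero-variance plane; z-normalization returns zeros")
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def he_to_synthetic_de(
    he: RGBImage, params: SyntheticDEParams | None = None, znormalize: bool = True
) -> DEImage:
    """Convert an 8-bit H&E image into a synthetic DRAQ5&Eosin pair.

    DRAQ5: nuclei-masked grayscale, inverted within the mask (background
    stays 0), plus Gaussian noise on the [0,1] scale, grayscale dilation,
    Gaussian smoothing, scaling to 12 bits and (optionally) z-normalization.
    Eosin: the same chain on the image with nuclei zeroed out first.
    Identical seeds give identical outputs.
    """
    params = params or SyntheticDEParams()
    rng = np.random.default_rng(params.rng_seed)
    nuclei = nuclei_mask_from_he(he, params.erosion_radius_px).astype(bool)

    gray = to_grayscale(he.data)
    draq5 = _de_channel_chain(
        _invert_preserving_zero(np.where(nuclei, gray, 0.0)), params, rng
    )

    he_no_nuclei = np.asarray(he.data, dtype=float).copy()
    he_no_nuclei[nuclei] = 0.0
    eosin = _de_channel_chain(
        _invert_preserving_zero(to_grayscale(he_no_nuclei)), params, rng
    )

    if znormalize:
        draq5, eosin = _znorm_plane(draq5), _znorm_plane(eosin)
    bit_depth = {255: 8, 4095: 12, 65535: 16}.get(params.scale_max, 12)
    return DEImage(
        draq5=ImagePlane(draq5, bit_depth, he.pixel_pitch_um, normalized=znormalize),
        eosin=ImagePlane(eosin, bit_depth, he.pixel_pitch_um, normalized=znormalize),
    )


# ---------------------------------------------------------------------------
# D&E -> synthetic H&E
# ---------------------------------------------------------------------------

def de_to_synthetic_he(de: DEImage, params: SyntheticHEParams | None = None) -> RGBImage:
    """Beer-Lambert recoloring of a D&E pair into a brightfield-like RGB.

    out_c = background * exp(-(odH_c * d^g1 + odE_c * e^g2)) per pixel, with
    d, e the channels normalized to [0,1] by their plane maxima.  An all-zero
    channel contributes no absorbance.  Pixel-separable and monotone
    non-increasing in each input channel.
    """
    params = params or SyntheticHEParams()
    d = np.asarray(de.draq5.data, dtype=float)
    e = np.asarray(de.eosin.data, dtype=float)
    d = np.clip(d, 0, None)
    e = np.clip(e, 0, None)
    dmax, emax = d.max(), e.max()
    dn = d / dmax if dmax > 0 else np.zeros_like(d)
    en = e / emax if emax > 0 else np.zeros_like(e)
    od = (
        params.od_hematoxylin_rgb[None, None, :] * (dn ** params.gamma_draq5)[..., None]
        + params.od_eosin_rgb[None, None, :] * (en ** params.gamma_eosin)[..., None]
    )
    rgb = params.background_level * np.exp(-od)
    return RGBImage(
        data=np.clip(np.rint(rgb), 0, 255).astype(np.uint8),
        pixel_pitch_um=de.pixel_pitch_um,
    )
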