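"""Acquisition-robustness harness: sharpness scoring and focus ranking,
a parametric acquisition forward model (defocus blur, averaging-dependent
noise, resampling, lens PSF), hierarchical phase-correlation mask
realignment, and per-condition robustness reports.

The forward model substitutes for physically re-imaging tissue: defocus is
a Gaussian blur with sigma_px = k * |focus offset in um|; detector noise is
additive Gaussian whose standard deviation scales as 1 / sqrt(averaging)
(confocal frame averaging); sampling density resamples to the requested
pixel pitch; the low-NA lens widens the PSF by the numerical-aperture
ratio.  Every constant is exposed as an argument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, shift as nd_shift, zoom as nd_zoom
from skimage.registration import phase_cross_correlation

from .errors import DegenerateInputError
from .metrics import MetricsReport, TaskSpec, evaluate
from .preprocess import clahe, resize, znorm
from .raster_io import DEImage, ImagePlane

FOCUS_OFFSETS_UM = (-5.0, -2.5, 0.0, 2.5, 5.0)
AVERAGING_LEVELS = (1, 2, 4, 8)
PIXEL_PITCHES_UM = (0.34, 0.52, 0.69)
PITCH_ALIASES = {0.35: 0.34}
LENSES = ("L20x_na08", "L10x_na045")
LENS_NA = {"L20x_na08": 0.8, "L10x_na045": 0.45}

DEFAULT_DEFOCUS_K = 0.8          # px of blur sigma per um of focus offset
DEFAULT_NOISE_SIGMA0 = 2400.0    # 12-bit counts of single-scan detector noise
DEFAULT_LENS_PSF_SIGMA = 0.8     # px; scaled by NA ratio for the low-NA lens
DEFAULT_WINDOWS = (64, 32, 16)
EMPTY_WINDOW_FRACTION = 0.01


@dataclass
class AcquisitionConfig:
    """One point on the standardization grid."""

    focus_offset_um: float = 0.0
    averaging: int = 8
    pixel_pitch_um: float = 0.52
    lens: str = "L20x_na08"
    custom: bool = False

    def __post_init__(self) -> None:
        self.pixel_pitch_um = PITCH_ALIASES.get(self.pixel_pitch_um, self.pixel_pitch_um)
        if self.custom:
            if self.pixel_pitch_um <= 0:
                raise ValueError("custom pixel pitch must be positive")
            return
        if self.focus_offset_um not in FOCUS_OFFSETS_UM:
            raise ValueError(f"focus offset must be one of {FOCUS_OFFSETS_UM}")
        if self.averaging not in AVERAGING_LEVELS:
            raise ValueError(f"averaging must be one of {AVERAGING_LEVELS}")
        if self.pixel_pitch_um not in PIXEL_PITCHES_UM:
            raise ValueError(f"pixel pitch must be one of {PIXEL_PITCHES_UM}")
        if self.lens not in LENSES:
            raise ValueError(f"lens must be one of {LENSES}")


# ---------------------------------------------------------------------------
# Sharpness
# ---------------------------------------------------------------------------

def sharpness_score(plane) -> float:
    """Mean gradient magnitude: average over pixels of sqrt(gx^2 + gy^2)
    with central-difference gradients.  Computed on raw (pre-equalization)
    intensities."""
    data = np.asarray(plane.data if isinstance(plane, ImagePlane) else plane, dtype=float)
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("sharpness needs at least a 2x2 plane")
    gy, gx = np.gradient(data)
    return float(np.mean(np.sqrt(gx * gx + gy * gy)))


def rank_focus(zstack: Sequence) -> tuple[list[int], int]:
    """Rank planes by descending sharpness (1 = sharpest; ties favour the
    earlier stack index).  Returns (ranks aligned with the stack, index of
    the sharpest plane)."""
    if len(zstack) < 1:
        raise ValueError("empty z-stack")
    scores = np.array([sharpness_score(p) for p in zstack])
    order = np.lexsort((np.arange(scores.size), -scores))
    ranks = np.empty(scores.size, dtype=int)
    ranks[order] = np.arange(1, scores.size + 1)
    return ranks.tolist(), int(order[0])


# ---------------------------------------------------------------------------
# Acquisition forward model
# ---------------------------------------------------------------------------

def _simulate_plane(
    plane: ImagePlane,
    cfg: AcquisitionConfig,
    noise_sigma0: float,
    rng: np.random.Generator,
    k: float,
    lens_psf_sigma: float,
) -> ImagePlane:
    data = np.asarray(plane.data, dtype=float)
    sigma_focus = k * abs(cfg.focus_offset_um)
    if sigma_focus > 0:
        data = gaussian_filter(data, sigma_focus)
    if cfg.lens == "L10x_na045":
        sigma_lens = lens_psf_sigma * (LENS_NA["L20x_na08"] / LENS_NA["L10x_na045"])
        data = gaussian_filter(data, sigma_lens)
    if cfg.pixel_pitch_um != plane.pixel_pitch_um:
        factor = plane.pixel_pitch_um / cfg.pixel_pitch_um
        data = nd_zoom(data, factor, order=1)
    if noise_sigma0 > 0:
        data = data + rng.normal(0.0, noise_sigma0 / np.sqrt(cfg.averaging), data.shape)
    data = np.clip(data, 0, plane.max_value)
    return ImagePlane(data, plane.bit_depth, cfg.pixel_pitch_um)


def simulate_acquisition(
    ideal: DEImage,
    cfg: AcquisitionConfig,
    noise_sigma0: float = DEFAULT_NOISE_SIGMA0,
    seed: int = 0,
    k: float = DEFAULT_DEFOCUS_K,
    lens_psf_sigma: float = DEFAULT_LENS_PSF_SIGMA,
) -> DEImage:
    """Apply the acquisition forward model to both channels.

    The identity configuration (focus 0, reference pitch, 20x lens) with
    ``noise_sigma0 = 0`` returns the input bit-exactly.
    """
    rng = np.random.default_rng(seed)
    draq5 = _simulate_plane(ideal.draq5, cfg, noise_sigma0, rng, k, lens_psf_sigma)
    eosin = _simulate_plane(ideal.eosin, cfg, noise_sigma0, rng, k, lens_psf_sigma)
    return DEImage(
        draq5=draq5,
        eosin=eosin,
        core_id=ideal.core_id,
        patient_id=ideal.patient_id,
        acquisition=cfg,
    )


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

def phase_shift(a: np.ndarray, b: np.ndarray) -> tuple[int, int]:
    """Integer displacement (dr, dc) of ``b`` relative to ``a`` via the
    argmax of the inverse normalized cross-power spectrum: if ``b`` is ``a``
    circularly shifted by (dr, dc), that shift is returned."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("phase_shift requires equal shapes")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateInputError("constant raster has no phase correlation")
    shift, _err, _phase = phase_cross_correlation(
        reference_image=b, moving_image=a, upsample_factor=1, normalization="phase"
    )
    return int(shift[0]), int(shift[1])


def hierarchical_register(
    moving_mask,
    reference,
    windows: Sequence[int] = DEFAULT_WINDOWS,
) -> np.ndarray:
    """Block-wise coarse-to-fine realignment of a mask onto a reference.

    For each window size (strictly decreasing), both rasters are tiled; the
    per-window integer shift is estimated by phase correlation (near-empty
    windows skipped, shifts capped at window/4 to prevent tearing) and the
    window content of the moving mask is replaced by the correspondingly
    shifted content, sourced with a margin so no pixels fall off block
    seams.  Later, smaller passes refine residual local shifts.
    """
    ref = np.asarray(reference.data if hasattr(reference, "data") else reference, dtype=float)
    mov = np.asarray(
        moving_mask.data if hasattr(moving_mask, "data") else moving_mask
    ).copy()
    if ref.shape != mov.shape:
        raise ValueError("moving mask and reference must share shape")
    if list(windows) != sorted(windows, reverse=True):
        raise ValueError("windows must be strictly decreasing")

    for w in windows:
        if w > min(ref.shape):
            warnings.warn(f"window {w} larger than image {ref.shape}; level skipped")
            continue
        cap = w // 4
        shifts = {}
        for r0 in range(0, ref.shape[0] - w + 1, w):
            for c0 in range(0, ref.shape[1] - w + 1, w):
                ref_win = ref[r0 : r0 + w, c0 : c0 + w]
                mov_win = mov[r0 : r0 + w, c0 : c0 + w]
                if (
                    np.count_nonzero(mov_win) < EMPTY_WINDOW_FRACTION * mov_win.size
                    or np.ptp(ref_win) == 0
                ):
                    continue
                try:
                    dr, dc = phase_shift(ref_win, mov_win)
                except DegenerateInputError:
                    continue
                if abs(dr) > cap or abs(dc) > cap:
                    continue
                if (dr, dc) != (0, 0):
                    shifts[(r0, c0)] = (dr, dc)
        if not shifts:
            continue
        src = mov.copy()
        for (r0, c0), (dr, dc) in shifts.items():
            m = cap  # margin large enough for any accepted shift
            pr0, pr1 = max(0, r0 - m), min(mov.shape[0], r0 + w + m)
            pc0, pc1 = max(0, c0 - m), min(mov.shape[1], c0 + w + m)
            patch = nd_shift(src[pr0:pr1, pc0:pc1], (-dr, -dc), order=0, cval=0)
            mov[r0 : r0 + w, c0 : c0 + w] = patch[
                r0 - pr0 : r0 - pr0 + w, c0 - pc0 : c0 - pc0 + w
            ]
    return mov


# ---------------------------------------------------------------------------
# Robustness report
# ---------------------------------------------------------------------------

def _preprocess_for_model(de: DEImage, input_shape) -> np.ndarray:
    chans = []
    for plane in (de.draq5, de.eosin):
        eq = clahe(plane)
        chans.append(znorm(resize(eq, input_shape[:2])))
    return np.stack(chans, axis=-1)


def robustness_report(
    model,
    phantom_set: Sequence[tuple[DEImage, object]],
    grid: Sequence[AcquisitionConfig],
    task: TaskSpec,
    input_shape: tuple[int, int] = (64, 64),
    noise_sigma0: float = DEFAULT_NOISE_SIGMA0,
    seed: int = 0,
    k: float = DEFAULT_DEFOCUS_K,
) -> pd.DataFrame:
    """Re-evaluate a trained model under every acquisition configuration.

    ``phantom_set`` pairs ideal-intensity D&E crops with their truth (binary
    labels for classifier tasks, 3-class rasters for segmentation).  Each
    configuration re-runs the acquisition simulation and the full
    CLAHE/z-norm preprocessing before inference; rows are long-form, one per
    configuration, carrying the config columns plus the task metrics.
    """
    rows = []
    for i, cfg in enumerate(grid):
        xs, truths = [], []
        for j, (de, truth) in enumerate(phantom_set):
            sim = simulate_acquisition(
                de, cfg, noise_sigma0=noise_sigma0, seed=seed * 100003 + i * 1009 + j, k=k
            )
            xs.append(_preprocess_for_model(sim, input_shape))
            if task is TaskSpec.CANCER_SEG:
                truths.append(resize(np.asarray(truth), input_shape[:2]))
            else:
                truths.append(int(truth))
        x = np.asarray(xs)
        preds = model.predict(x)
        if task is TaskSpec.CANCER_SEG:
            report: MetricsReport = evaluate(task, list(preds), truths)
        else:
            report = evaluate(task, preds.ravel(), truths)
        row = {
            "focus_offset_um": cfg.focus_offset_um,
            "averaging": cfg.averaging,
            "pixel_pitch_um": cfg.pixel_pitch_um,
            "lens": cfg.lens,
        }
        row.update(report.as_row())
        rows.append(row)
    return pd.DataFrame(rows)
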