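"""Ground-truth construction: epithelial gating of pathologist annotations,
crop-level label assignment, slide-level grade presence, stain
normalization, epithelium prediction plumbing, and task label mappings.

Label assignment follows three removal rules applied to the gated
annotation inside each crop: a crop with no annotated pixel is removed; a
crop whose predominant (modal non-background) class covers less than 15% of
all crop pixels is removed; a crop whose predominant class is less than 75%
of the annotated (non-background) pixels is removed.  Anything surviving
gets the predominant class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Optional, Union

import numpy as np
from sklearn.decomposition import NMF

from .errors import ConfigurationError
from .metrics import BINARY_THRESHOLD, TaskSpec
from .preprocess import clahe, crop_boxes, resize, tissue_mask, znorm
from .raster_io import (
    Box,
    DEImage,
    EpithelialMask,
    LabelMask,
    RGBImage,
    crop_to_box,
)
from .virtual_stain import to_grayscale

#: Sentinel emitted by map_to_task for crops outside a binary task's pair.
EXCLUDED = -1

#: Gleason grouping used by all binary tasks.
LOW_GRADE_CLASSES = frozenset({2})                 # GP3
HIGH_GRADE_CLASSES = frozenset({3, 4, 5, 6})       # GP4, cribriform, glomeruloid, GP5
HEALTHY_CLASS = 1
CANCER_CLASSES = frozenset({2, 3, 4, 5, 6})

MIN_PREDOMINANT_CROP_FRACTION = 0.15   # of all crop pixels
MIN_PREDOMINANT_CLASS_FRACTION = 0.75  # of annotated pixels
DEFAULT_GRADE_PRESENCE_FRACTION = 0.05


class RemovalReason(str, Enum):
    NO_ANNOTATION = "no_annotation"
    BELOW_15PCT = "below_15pct"
    BELOW_75PCT = "below_75pct"


@dataclass(frozen=True)
class Removed:
    reason: RemovalReason


@dataclass
class CropRecord:
    """One analysis tile: its pixels, provenance, and labels."""

    box: Box
    draq5_crop: np.ndarray
    eosin_crop: np.ndarray
    core_id: str
    patient_id: str
    raw_label: Union[int, Removed]
    task_labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if isinstance(self.raw_label, Removed) and self.task_labels:
            raise ValueError("removed crops carry no task labels")

    @property
    def removed(self) -> bool:
        return isinstance(self.raw_label, Removed)


# ---------------------------------------------------------------------------
# Gating and crop labeling
# ---------------------------------------------------------------------------

def gate_annotation(ann: LabelMask, epi: EpithelialMask) -> LabelMask:
    """Zero out annotation outside the epithelial mask (idempotent)."""
    if ann.shape != epi.shape:
        raise ValueError("annotation and epithelium mask shapes differ")
    gated = np.where(np.asarray(epi.data) == 1, np.asarray(ann.data), 0)
    return LabelMask(gated, legend=ann.legend)


def assign_crop_label(gated_crop_mask: LabelMask) -> Union[int, Removed]:
    """Predominant-class label for one crop, or a removal reason.

    Modal ties break to the lowest class id; any two-way tie necessarily
    fails the 75% rule, so the tie-break never changes which crops survive.
    """
    data = np.asarray(gated_crop_mask.data)
    total = data.size
    fg = data[data > 0]
    if fg.size == 0:
        return Removed(RemovalReason.NO_ANNOTATION)
    classes, counts = np.unique(fg, return_counts=True)
    modal_idx = int(np.argmax(counts))  # first max -> lowest class id
    modal_class, modal_count = int(classes[modal_idx]), int(counts[modal_idx])
    if modal_count < MIN_PREDOMINANT_CROP_FRACTION * total:
        return Removed(RemovalReason.BELOW_15PCT)
    if modal_count < MIN_PREDOMINANT_CLASS_FRACTION * fg.size:
        return Removed(RemovalReason.BELOW_75PCT)
    return modal_class


def grade_presence(
    slide_mask: LabelMask,
    epi: EpithelialMask,
    min_frac: float = DEFAULT_GRADE_PRESENCE_FRACTION,
) -> set[int]:
    """Classes covering at least ``min_frac`` of the epithelial pixels."""
    gated = gate_annotation(slide_mask, epi)
    total_epi = int(np.count_nonzero(np.asarray(epi.data) == 1))
    if total_epi == 0:
        return set()
    data = np.asarray(gated.data)
    present = set()
    for cls in np.unique(data[data > 0]):
        if np.count_nonzero(data == cls) >= min_frac * total_epi:
            present.add(int(cls))
    return present


def map_to_task(raw_label_or_mask, task: TaskSpec):
    """Map a legend class (or label raster) onto a task's target space.

    Binary tasks: the first-named class of the task maps to 1, the
    second-named to 0; anything else returns the ``EXCLUDED`` sentinel.
    CANCER_SEG maps rasters to {0: background/stroma, 1: healthy epithelium,
    2: cancerous epithelium}.
    """
    if task is TaskSpec.CANCER_SEG:
        data = np.asarray(
            raw_label_or_mask.data if isinstance(raw_label_or_mask, LabelMask) else raw_label_or_mask
        )
        out = np.zeros(data.shape, dtype=np.int64)
        out[data == HEALTHY_CLASS] = 1
        out[np.isin(data, list(CANCER_CLASSES))] = 2
        return out

    label = int(raw_label_or_mask)
    if task is TaskSpec.LOW_VS_HEALTHY:
        pos, neg = LOW_GRADE_CLASSES, {HEALTHY_CLASS}
    elif task is TaskSpec.HIGH_VS_HEALTHY:
        pos, neg = HIGH_GRADE_CLASSES, {HEALTHY_CLASS}
    elif task is TaskSpec.HIGH_VS_LOW:
        pos, neg = HIGH_GRADE_CLASSES, LOW_GRADE_CLASSES
    else:  # pragma: no cover
        raise ValueError(f"unknown task {task}")
    if label in pos:
        return 1
    if label in neg:
        return 0
    return EXCLUDED


# ---------------------------------------------------------------------------
# Stain normalization (two-stain non-negative factorization)
# ---------------------------------------------------------------------------

def luminosity_standardize(img: RGBImage, percentile: float = 95.0) -> RGBImage:
    """Scale so the given luminance percentile maps to white."""
    data = np.asarray(img.data, dtype=float)
    p = float(np.percentile(to_grayscale(data), percentile))
    if p <= 0:
        return RGBImage(data.astype(np.uint8), img.pixel_pitch_um)
    out = np.clip(data * (255.0 / p), 0, 255)
    return RGBImage(out.astype(np.uint8), img.pixel_pitch_um)


def _rgb_to_od(data: np.ndarray) -> np.ndarray:
    return -np.log((np.asarray(data, dtype=float) + 1.0) / 256.0)


def _od_to_rgb(od: np.ndarray) -> np.ndarray:
    return np.clip(256.0 * np.exp(-od) - 1.0, 0, 255)


def _fit_stains(od_pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-stain non-negative factorization OD ~ C @ S.

    Multiplicative-update NMF warm-started at the conventional
    hematoxylin/eosin optical-density directions, so the two factors
    converge to the image's actual stain basis rather than an arbitrary
    rotation of it.  Returns (concentrations n x 2, stains 2 x 3 with
    unit-norm rows, hematoxylin-like first by descending red absorbance).
    """
    from .virtual_stain import OD_EOSIN_RGB, OD_HEMATOXYLIN_RGB

    od = np.clip(od_pixels, 0, None)
    s0 = np.stack([OD_HEMATOXYLIN_RGB, OD_EOSIN_RGB]).astype(float)
    s0 /= np.linalg.norm(s0, axis=1, keepdims=True)
    w0 = np.clip(od @ np.linalg.pinv(s0), 1e-6, None)
    model = NMF(
        n_components=2, init="custom", solver="mu", max_iter=500,
        tol=1e-7, random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter on tiny inputs
        c = model.fit_transform(od, W=w0, H=s0.copy())
    s = model.components_
    norms = np.linalg.norm(s, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    s = s / norms
    c = c * norms.T
    order = np.argsort(-s[:, 0])  # hematoxylin absorbs red strongly; eosin barely
    return c[:, order], s[order]


def stain_normalize(src: RGBImage, target: RGBImage) -> RGBImage:
    """Map the source's stain appearance onto the target's.

    Both images are luminosity standardized, decomposed in optical density
    as OD ~ C @ S with non-negative two-stain factors, the source stain
    matrix is replaced by the target's, per-stain concentrations are scaled
    to match the target's 99th percentiles, and the result re-exponentiated.
    """
    src_std = luminosity_standardize(src)
    tgt_std = luminosity_standardize(target)
    src_od = _rgb_to_od(src_std.data).reshape(-1, 3)
    tgt_od = _rgb_to_od(tgt_std.data).reshape(-1, 3)
    if np.percentile(src_od.sum(axis=1), 99) < 0.05:
        warnings.warn("near-white source; returning luminosity-standardized image")
        return src_std
    c_src, _s_src = _fit_stains(src_od)
    c_tgt, s_tgt = _fit_stains(tgt_od)
    for j in range(2):
        p_src = np.percentile(c_src[:, j], 99)
        p_tgt = np.percentile(c_tgt[:, j], 99)
        if p_src > 0:
            c_src[:, j] *= p_tgt / p_src
    od_new = (c_src @ s_tgt).reshape(src_std.data.shape)
    return RGBImage(_od_to_rgb(od_new).astype(np.uint8), src.pixel_pitch_um)


# ---------------------------------------------------------------------------
# Epithelium prediction
# ---------------------------------------------------------------------------

def predict_epithelium(
    he: RGBImage,
    model,
    target_ref: RGBImage,
    crop_edge_um: float = 245.52,
    model_input: tuple[int, int] = (256, 256),
) -> EpithelialMask:
    """Run the epithelium segmentation chain over a synthetic H&E slide.

    Per 245.52-um crop: luminosity standardization, stain normalization
    against ``target_ref``, per-channel CLAHE, division by 255, nearest
    resize to the model input, inference, nearest resize back.  The final
    mask is thresholded at 0.5 and gated by the tissue mask.

    ``model`` is any callable mapping (H, W, 3) float arrays to a
    probability map; trained U-Nets and test oracles plug in equally.
    """
    predict: Optional[Callable] = getattr(model, "predict", None) or model
    if not callable(predict):
        raise ConfigurationError("model must be callable or expose .predict")

    tmask = tissue_mask(he)
    out = np.zeros(he.shape, dtype=np.uint8)
    for box in crop_boxes(he.shape, he.pixel_pitch_um, crop_edge_um):
        r0, r1, c0, c1 = box
        crop = RGBImage(crop_to_box(he.data, box), he.pixel_pitch_um)
        norm = stain_normalize(crop, target_ref)
        chans = np.stack([clahe(norm.data[..., ch]) for ch in range(3)], axis=-1)
        small = resize(chans.astype(np.float64), model_input)
        prob = np.asarray(predict(small), dtype=float)
        prob = np.squeeze(prob)
        if prob.shape != tuple(model_input):
            raise ConfigurationError(
                f"model output shape {prob.shape} does not match input {model_input}"
            )
        back = resize(prob, (r1 - r0, c1 - c0))
        out[r0:r1, c0:c1] = (back >= BINARY_THRESHOLD).astype(np.uint8)
    out &= tmask.astype(np.uint8)
    return EpithelialMask(out)


# ---------------------------------------------------------------------------
# Crop dataset construction
# ---------------------------------------------------------------------------

def build_crop_records(
    de: DEImage,
    gated: LabelMask,
    crop_edge_um: float = 245.52,
    target_size: tuple[int, int] = (256, 256),
) -> list[CropRecord]:
    """Tile a (background-corrected, CLAHE'd) D&E image and its gated
    annotation into labeled crop records.

    Channel crops are nearest-resized to ``target_size`` and z-normalized;
    surviving records carry the CANCER_SEG raster plus every binary task
    label (possibly the EXCLUDED sentinel).
    """
    records = []
    for box in crop_boxes(de.shape, de.pixel_pitch_um, crop_edge_um):
        mask_crop = LabelMask(crop_to_box(gated.data, box), legend=gated.legend)
        label = assign_crop_label(mask_crop)
        d = znorm(resize(crop_to_box(np.asarray(de.draq5.data, float), box), target_size))
        e = znorm(resize(crop_to_box(np.asarray(de.eosin.data, float), box), target_size))
        task_labels = {}
        if not isinstance(label, Removed):
            for task in (TaskSpec.LOW_VS_HEALTHY, TaskSpec.HIGH_VS_HEALTHY, TaskSpec.HIGH_VS_LOW):
                task_labels[task] = map_to_task(label, task)
            task_labels[TaskSpec.CANCER_SEG] = map_to_task(
                resize(np.asarray(mask_crop.data), target_size), TaskSpec.CANCER_SEG
            )
        records.append(
            CropRecord(
                box=box,
                draq5_crop=d,
                eosin_crop=e,
                core_id=de.core_id,
                patient_id=de.patient_id,
                raw_label=label,
                task_labels=task_labels,
            )
        )
    return records
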