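"""Seeded synthetic tissue phantom: gland-structured cores in both the
fluorescence (DRAQ5&Eosin) and brightfield (synthetic H&E) modalities, with
pixel-perfect class and epithelium ground truth.

Morphology archetypes are deliberate caricatures of Gleason architecture,
tuned to make the downstream classification/segmentation tasks learnable by
small models rather than to be histologically faithful:

* Healthy — large round glands, a wide lumen ringed by a single sparse
  layer of nuclei;
* GP3 — small, well-separated glands with small lumens;
* GP4 — fused clusters of several small glands sharing one epithelial
  island with multiple lumens (cribriform-like), dense nuclei;
* GP5 — nuclear sheets: lumen-free epithelial islands filled with densely
  packed nuclei.

DRAQ5 carries the nuclei, Eosin carries cytoplasm and a textured stroma;
both are 12-bit.  Every core is bit-reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .raster_io import (
    DEImage,
    EpithelialMask,
    ImagePlane,
    LabelMask,
    RGBImage,
    write_manifest,
    write_mask,
    write_plane,
)
from .virtual_stain import SyntheticHEParams, de_to_synthetic_he

MAX_12BIT = 4095


@dataclass
class PhantomParams:
    canvas_px: tuple[int, int] = (1024, 1024)
    pixel_pitch_um: float = 0.52
    n_glands: int = 80                     # upper bound on placed glands
    target_epithelium_frac: float = 0.45   # stop placing once reached
    gland_radius_um: tuple[float, float] = (15.0, 45.0)
    lumen_fraction: float = 0.45
    nucleus_radius_um: tuple[float, float] = (2.2, 3.2)
    class_mix: dict[int, float] = field(
        default_factory=lambda: {1: 0.4, 2: 0.2, 3: 0.2, 6: 0.2}
    )
    fusion_prob: float = 0.9
    sheet_prob: float = 0.9
    stroma_texture_scale: float = 12.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"class_mix probabilities must sum to 1, got {total}")
        if min(self.gland_radius_um) <= 0 or min(self.nucleus_radius_um) <= 0:
            raise ValueError("radii must be positive")
        for p in (self.fusion_prob, self.sheet_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class CoreSample:
    de: DEImage
    labels: LabelMask
    epithelium: EpithelialMask
    he: RGBImage


# ---------------------------------------------------------------------------
# Drawing primitives
# ---------------------------------------------------------------------------

def _disk_indices(shape, cy, cx, r):
    r_int = int(np.ceil(r))
    y0, y1 = max(0, int(cy) - r_int), min(shape[0], int(cy) + r_int + 1)
    x0, x1 = max(0, int(cx) - r_int), min(shape[1], int(cx) + r_int + 1)
    if y0 >= y1 or x0 >= x1:
        return None
    yy, xx = np.ogrid[y0:y1, x0:x1]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    return (slice(y0, y1), slice(x0, x1)), mask


def _paint_disk(arr, cy, cx, r, value):
    hit = _disk_indices(arr.shape, cy, cx, r)
    if hit is None:
        return
    sl, mask = hit
    arr[sl][mask] = value


def _ring_nuclei(rng, cy, cx, radius, nuc_r, layers=1, jitter=0.3):
    """Nucleus centers along one or more concentric rings."""
    pts = []
    for layer in range(layers):
        rr = radius + layer * 2.0 * nuc_r
        n = max(4, int(2 * np.pi * rr / (2.2 * nuc_r)))
        phase = rng.uniform(0, 2 * np.pi)
        for i in range(n):
            a = phase + 2 * np.pi * i / n
            pts.append(
                (
                    cy + rr * np.sin(a) + rng.normal(0, jitter * nuc_r),
                    cx + rr * np.cos(a) + rng.normal(0, jitter * nuc_r),
                )
            )
    return pts


def _scatter_nuclei(rng, cy, cx, radius, nuc_r, density=0.35):
    """Dense random nucleus centers filling a disk (GP5 sheets)."""
    area = np.pi * radius * radius
    n = int(density * area / (np.pi * nuc_r * nuc_r))
    pts = []
    for _ in range(n):
        rr = radius * np.sqrt(rng.uniform())
        a = rng.uniform(0, 2 * np.pi)
        pts.append((cy + rr * np.sin(a), cx + rr * np.cos(a)))
    return pts


# ---------------------------------------------------------------------------
# Core generation
# ---------------------------------------------------------------------------

def generate_core(params: PhantomParams, return_meta: bool = False):
    """Render one phantom core: (DEImage, LabelMask, EpithelialMask, RGBImage).

    With ``return_meta=True`` a fifth element is appended: a dict with the
    realized per-gland class list (placement-rejected glands excluded)."""
    rows, cols = params.canvas_px
    px = params.pixel_pitch_um
    r_lo, r_hi = (r / px for r in params.gland_radius_um)
    if min(rows, cols) < 2 * r_hi:
        raise ValueError(
            f"canvas {params.canvas_px} too small for a gland of radius {r_hi:.0f} px"
        )
    rng = np.random.default_rng(params.rng_seed)
    nuc_lo, nuc_hi = (r / px for r in params.nucleus_radius_um)

    draq5 = np.zeros((rows, cols))
    eosin = np.zeros((rows, cols))
    labels = np.zeros((rows, cols), dtype=np.int64)
    epi = np.zeros((rows, cols), dtype=np.uint8)

    # textured eosinophilic stroma
    texture = gaussian_filter(rng.normal(size=(rows, cols)), params.stroma_texture_scale)
    tstd = texture.std() or 1.0
    eosin += 900 + 350 * texture / tstd
    draq5 += rng.uniform(30, 90) + 25 * gaussian_filter(
        rng.normal(size=(rows, cols)), 2.0
    )

    classes = sorted(params.class_mix)
    probs = np.array([params.class_mix[c] for c in classes])
    placed: list[tuple[float, float, float]] = []
    gland_classes: list[int] = []
    nuclei_pts: list[tuple[float, float, float]] = []  # (y, x, r)

    def try_place(radius, min_gap=0.95, tries=60):
        for _ in range(tries):
            cy = rng.uniform(radius, rows - radius)
            cx = rng.uniform(radius, cols - radius)
            if all(
                (cy - py) ** 2 + (cx - px_) ** 2 > (min_gap * (radius + pr)) ** 2
                for py, px_, pr in placed
            ):
                return cy, cx
        return None

    def paint_gland(cy, cx, radius, cls, lumen_frac, nuc_layers):
        hit = _disk_indices(labels.shape, cy, cx, radius)
        if hit is None:
            return
        sl, mask = hit
        labels[sl][mask] = cls
        epi[sl][mask] = 1
        eosin[sl][mask] = 1900 + rng.normal(0, 80)
        lum_r = lumen_frac * radius
        if lumen_frac > 0:
            _paint_disk(eosin, cy, cx, lum_r, 150.0)
        nuc_r = rng.uniform(nuc_lo, nuc_hi)
        for (ny, nx) in _ring_nuclei(rng, cy, cx, lum_r + nuc_r, nuc_r, layers=nuc_layers):
            nuclei_pts.append((ny, nx, rng.uniform(nuc_lo, nuc_hi)))

    for _ in range(params.n_glands):
        if epi.mean() >= params.target_epithelium_frac:
            break
        cls = int(rng.choice(classes, p=probs))
        if cls == 1:  # Healthy: large gland, wide lumen, sparse single ring
            radius = rng.uniform(0.75 * r_hi, r_hi)
            pos = try_place(radius)
            if pos is None:
                continue
            placed.append((*pos, radius))
            gland_classes.append(cls)
            paint_gland(*pos, radius, 1, max(params.lumen_fraction, 0.5), 1)
        elif cls == 2:  # GP3: small separated gland
            radius = rng.uniform(r_lo, 0.5 * r_hi)
            pos = try_place(radius, min_gap=1.15)
            if pos is None:
                continue
            placed.append((*pos, radius))
            gland_classes.append(cls)
            paint_gland(*pos, radius, 2, 0.35, 1)
        elif cls == 3:  # GP4: fused cluster with several small lumens
            cluster_r = rng.uniform(0.6 * r_hi, 0.85 * r_hi)
            pos = try_place(cluster_r)
            if pos is None:
                continue
            placed.append((*pos, cluster_r))
            gland_classes.append(cls)
            cy, cx = pos
            fused = rng.uniform() < params.fusion_prob
            n_sub = int(rng.integers(3, 6)) if fused else 1
            hit = _disk_indices(labels.shape, cy, cx, cluster_r)
            if hit is not None:
                sl, mask = hit
                labels[sl][mask] = 3
                epi[sl][mask] = 1
                eosin[sl][mask] = 1900 + rng.normal(0, 80)
            nuc_r = rng.uniform(nuc_lo, nuc_hi)
            for _ in range(n_sub):
                rr = rng.uniform(0, 0.55 * cluster_r)
                a = rng.uniform(0, 2 * np.pi)
                sy, sx = cy + rr * np.sin(a), cx + rr * np.cos(a)
                lum = rng.uniform(0.12, 0.2) * cluster_r
                _paint_disk(eosin, sy, sx, lum, 150.0)
                for (ny, nx) in _ring_nuclei(rng, sy, sx, lum + nuc_r, nuc_r, layers=2):
                    nuclei_pts.append((ny, nx, rng.uniform(nuc_lo, nuc_hi)))
        else:  # GP5: nuclear sheet without lumens
            radius = rng.uniform(0.55 * r_hi, 0.8 * r_hi)
            pos = try_place(radius)
            if pos is None:
                continue
            placed.append((*pos, radius))
            gland_classes.append(cls)
            cy, cx = pos
            hit = _disk_indices(labels.shape, cy, cx, radius)
            if hit is not None:
                sl, mask = hit
                labels[sl][mask] = 6
                epi[sl][mask] = 1
                eosin[sl][mask] = 1700 + rng.normal(0, 80)
            nuc_r = rng.uniform(nuc_lo, nuc_hi)
            if rng.uniform() < params.sheet_prob:
                pts = _scatter_nuclei(rng, cy, cx, 0.95 * radius, nuc_r)
            else:
                pts = _ring_nuclei(rng, cy, cx, 0.5 * radius, nuc_r, layers=3)
            for (ny, nx) in pts:
                nuclei_pts.append((ny, nx, rng.uniform(nuc_lo, nuc_hi)))

    for (ny, nx, nr) in nuclei_pts:
        _paint_disk(draq5, ny, nx, nr, rng.normal(3100, 250))
        hit = _disk_indices(eosin.shape, ny, nx, nr)
        if hit is not None:
            sl, mask = hit
            eosin[sl][mask] *= 0.65

    draq5 = np.clip(gaussian_filter(draq5, 0.8), 0, MAX_12BIT)
    eosin = np.clip(gaussian_filter(eosin, 0.8), 0, MAX_12BIT)

    de = DEImage(
        draq5=ImagePlane(draq5, 12, px),
        eosin=ImagePlane(eosin, 12, px),
    )
    label_mask = LabelMask(labels)
    epi_mask = EpithelialMask(epi)
    he = de_to_synthetic_he(de, SyntheticHEParams())
    if return_meta:
        return de, label_mask, epi_mask, he, {"gland_classes": gland_classes}
    return de, label_mask, epi_mask, he


def generate_zstack(
    core: DEImage,
    offsets_um: tuple[float, ...] = (-5.0, -2.5, 0.0, 2.5, 5.0),
    k: float = 0.8,
) -> tuple[list[ImagePlane], list[ImagePlane]]:
    """Defocus stack per channel: Gaussian blur with sigma = k * |offset|;
    the zero-offset plane is the input unchanged."""
    if not np.all(np.isfinite(offsets_um)):
        raise ValueError("offsets must be finite")
    d_planes, e_planes = [], []
    for off in offsets_um:
        sigma = k * abs(off)
        for src, dst in ((core.draq5, d_planes), (core.eosin, e_planes)):
            data = np.asarray(src.data, dtype=float)
            blurred = data.copy() if sigma == 0 else gaussian_filter(data, sigma)
            dst.append(ImagePlane(blurred, src.bit_depth, src.pixel_pitch_um))
    return d_planes, e_planes


def generate_cohort(
    n_cores: int,
    params_template: PhantomParams | None = None,
    seed: int = 0,
    cores_per_patient: int = 1,
    dominant_frac: float = 0.95,
    out_dir=None,
) -> tuple[list[CoreSample], pd.DataFrame]:
    """Generate a cohort of cores with per-core derived seeds and distinct
    patient identifiers; optionally write rasters + manifest to disk.

    Mirroring how tissue-microarray cores tend to be dominated by a single
    Gleason pattern, each core draws a dominant class from the template mix
    and concentrates ``dominant_frac`` of its gland probability on it; the
    remainder is spread over the other classes proportionally.  Set
    ``dominant_frac=0`` for fully mixed cores.
    """
    if n_cores < 1:
        raise ValueError("n_cores must be >= 1")
    template = params_template or PhantomParams()
    rng = np.random.default_rng(seed)
    core_seeds = rng.integers(0, 2 ** 31 - 1, size=n_cores)
    mix_classes = sorted(template.class_mix)
    mix_probs = np.array([template.class_mix[c] for c in mix_classes])
    samples, rows = [], []
    for i in range(n_cores):
        core_id = f"core{i:03d}"
        patient_id = f"patient{i // cores_per_patient:03d}"
        core_mix = dict(template.class_mix)
        if dominant_frac > 0:
            dom = int(rng.choice(mix_classes, p=mix_probs))
            rest = {c: p for c, p in template.class_mix.items() if c != dom}
            rest_total = sum(rest.values()) or 1.0
            core_mix = {
                c: (dominant_frac if c == dom else (1 - dominant_frac) * p / rest_total)
                for c, p in template.class_mix.items()
            }
        de, labels, epi, he = generate_core(
            replace(template, rng_seed=int(core_seeds[i]), class_mix=core_mix)
        )
        de.core_id, de.patient_id = core_id, patient_id
        samples.append(CoreSample(de, labels, epi, he))
        row = {
            "core_id": core_id,
            "patient_id": patient_id,
            "path_draq5": "",
            "path_eosin": "",
            "path_mask": "",
            "pixel_pitch_um": template.pixel_pitch_um,
        }
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            row["path_draq5"] = str(write_plane(_as_int(de.draq5), out / f"{core_id}_draq5.tif"))
            row["path_eosin"] = str(write_plane(_as_int(de.eosin), out / f"{core_id}_eosin.tif"))
            row["path_mask"] = str(
                write_mask(labels, out / f"{core_id}_mask.tif", out / f"{core_id}_legend.json")
            )
        rows.append(row)
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        write_manifest(manifest, Path(out_dir) / "manifest.csv")
    return samples, manifest


def _as_int(plane: ImagePlane) -> ImagePlane:
    return ImagePlane(
        np.rint(plane.data).astype(np.uint16), plane.bit_depth, plane.pixel_pitch_um
    )
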