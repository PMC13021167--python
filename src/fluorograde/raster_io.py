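"""Raster, mask and manifest I/O with fixed coordinate and value conventions.

Coordinate convention used by the whole package
-----------------------------------------------
Rasters are row-major 2-D arrays, origin top-left, 0-based indices.  Every
box/crop is half-open ``[r0, r1) x [c0, c1)`` in pixel coordinates; the
helpers :func:`validate_box` and :func:`crop_to_box` assert this convention
so no other module re-implements it.

Value conventions
-----------------
Intensity planes carry a *nominal* bit depth of 8, 12 or 16 bits.  12-bit
data (the native depth of confocal exports) is stored on disk inside a
16-bit container with values unscaled; the nominal depth travels with the
in-memory object, not the file.  Label masks are single-channel rasters with
a sidecar legend (a JSON key -> name table); palettes are never inferred.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError

#: Fixed annotation legend: six foreground categories plus background.
LEGEND: dict[int, str] = {
    0: "background",
    1: "Healthy",
    2: "GP3",
    3: "GP4",
    4: "Cribriform",
    5: "Glomeruloid",
    6: "GP5",
}

#: Legend for binary epithelium masks.
BINARY_LEGEND: dict[int, str] = {0: "non_epithelium", 1: "epithelium"}

MANIFEST_COLUMNS = [
    "core_id",
    "patient_id",
    "path_draq5",
    "path_eosin",
    "path_mask",
    "pixel_pitch_um",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ImagePlane:
    """A single 2-D intensity raster with physical pixel size.

    Parameters
    ----------
    data : ndarray, shape (rows, cols)
        Intensity values in ``[0, 2**bit_depth - 1]``.
    bit_depth : {8, 12, 16}
        Nominal acquisition depth.  12-bit data lives in a 16-bit container.
    pixel_pitch_um : float
        Edge length of one pixel in micrometres.
    """

    data: np.ndarray
    bit_depth: int = 16
    pixel_pitch_um: float = 0.52
    #: True for planes that have been z-normalized (mean 0, std 1); such
    #: planes are no longer bounded by the bit-depth range.
    normalized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise FormatError(f"ImagePlane requires a 2-D raster, got shape {self.data.shape}")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError(f"bit_depth must be 8, 12 or 16, got {self.bit_depth}")
        if not self.pixel_pitch_um > 0:
            raise ValueError("pixel_pitch_um must be positive")
        if not self.normalized:
            vmax = float(np.max(self.data)) if self.data.size else 0.0
            vmin = float(np.min(self.data)) if self.data.size else 0.0
            if vmin < 0 or vmax > 2 ** self.bit_depth - 1:
                raise ValueError(
                    f"values [{vmin}, {vmax}] exceed the {self.bit_depth}-bit range"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def max_value(self) -> int:
        return 2 ** self.bit_depth - 1


@dataclass
class RGBImage:
    """8-bit RGB raster; pure white (255,255,255) is background by convention."""

    data: np.ndarray
    pixel_pitch_um: float = 0.52

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise FormatError(f"RGBImage requires (rows, cols, 3), got {self.data.shape}")
        if self.data.min() < 0 or self.data.max() > 255:
            raise ValueError("RGB values must lie in [0, 255]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]


@dataclass
class DEImage:
    """Paired DRAQ5 (nuclear) and Eosin (cytoplasmic) fluorescence planes."""

    draq5: ImagePlane
    eosin: ImagePlane
    core_id: str = ""
    patient_id: str = ""
    acquisition: Optional[object] = None  # AcquisitionConfig, kept loose to avoid a cycle

    def __post_init__(self) -> None:
        if self.draq5.shape != self.eosin.shape:
            raise ValueError("DRAQ5 and Eosin planes must share shape")
        if self.draq5.bit_depth != self.eosin.bit_depth:
            raise ValueError("DRAQ5 and Eosin planes must share bit depth")
        if self.draq5.pixel_pitch_um != self.eosin.pixel_pitch_um:
            raise ValueError("DRAQ5 and Eosin planes must share pixel pitch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.draq5.shape

    @property
    def pixel_pitch_um(self) -> float:
        return self.draq5.pixel_pitch_um


@dataclass
class LabelMask:
    """Integer raster over the annotation legend (class 0 = background)."""

    data: np.ndarray
    legend: dict[int, str] = field(default_factory=lambda: dict(LEGEND))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise FormatError("LabelMask requires a 2-D raster")
        bad = np.setdiff1d(np.unique(self.data), np.array(sorted(self.legend)))
        if bad.size:
            raise FormatError(f"mask contains values absent from the legend: {bad.tolist()}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class EpithelialMask:
    """Binary raster: 1 = epithelium, 0 = everything else."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise FormatError("EpithelialMask requires a 2-D raster")
        if not np.isin(np.unique(self.data), (0, 1)).all():
            raise FormatError("EpithelialMask values must be 0 or 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Box helpers (the package-wide coordinate contract)
# ---------------------------------------------------------------------------

Box = tuple[int, int, int, int]


def validate_box(box: Box, shape: tuple[int, int]) -> Box:
    """Assert a half-open ``(r0, r1, c0, c1)`` box lies inside ``shape``."""
    r0, r1, c0, c1 = (int(v) for v in box)
    if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
        raise ValueError(f"box {box} is not a valid half-open box inside {shape}")
    return r0, r1, c0, c1


def crop_to_box(raster: np.ndarray, box: Box) -> np.ndarray:
    """Extract the half-open box ``[r0,r1) x [c0,c1)`` from a raster."""
    r0, r1, c0, c1 = validate_box(box, raster.shape[:2])
    return raster[r0:r1, c0:c1]


# ---------------------------------------------------------------------------
# Plane I/O
# ---------------------------------------------------------------------------

def _container_dtype(bit_depth: int) -> np.dtype:
    return np.dtype(np.uint8) if bit_depth == 8 else np.dtype(np.uint16)


def read_plane(path, pixel_pitch_um: float, nominal_bit_depth: int = 16) -> ImagePlane:
    """Read a single-page grayscale TIFF/PNG as an :class:`ImagePlane`.

    ``nominal_bit_depth`` declares 12-bit data stored in a 16-bit container
    (there is no file-level flag for it); values are never rescaled.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = iio.imread(path)
    if data.ndim != 2:
        raise FormatError(f"{path} is not single-channel grayscale (shape {data.shape})")
    if data.dtype == np.uint8:
        bit_depth = 8
    else:
        bit_depth = nominal_bit_depth if nominal_bit_depth in (12, 16) else 16
    return ImagePlane(data=data, bit_depth=bit_depth, pixel_pitch_um=pixel_pitch_um)


def write_plane(plane: ImagePlane, path) -> Path:
    """Write a plane losslessly; 12-bit data goes unscaled into uint16."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    data = np.asarray(plane.data)
    out = np.rint(data).astype(_container_dtype(plane.bit_depth))
    if not np.array_equal(out, data):
        raise ValueError("plane data is not integral; lossless write impossible")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)
    return path


def read_zstack(path, pixel_pitch_um: float, nominal_bit_depth: int = 16) -> list[ImagePlane]:
    """Read a multi-page TIFF as a z-stack; page order is acquisition order
    (-5, -2.5, 0, +2.5, +5 um)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    return [
        ImagePlane(p, bit_depth=nominal_bit_depth, pixel_pitch_um=pixel_pitch_um)
        for p in pages
    ]


def write_zstack(planes: list[ImagePlane], path) -> Path:
    path = Path(path)
    stack = np.stack([np.rint(p.data).astype(_container_dtype(p.bit_depth)) for p in planes])
    tifffile.imwrite(path, stack)
    return path


# ---------------------------------------------------------------------------
# Mask I/O (raster + sidecar legend)
# ---------------------------------------------------------------------------

def write_legend(legend: dict[int, str], path) -> Path:
    path = Path(path)
    path.write_text(json.dumps({str(k): v for k, v in legend.items()}, indent=0))
    return path


def read_legend(path) -> dict[int, str]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    raw = json.loads(path.read_text())
    return {int(k): str(v) for k, v in raw.items()}


def read_mask(raster_path, legend_path):
    """Read an indexed mask raster and validate it against its legend.

    A legend with keys exactly ``{0, 1}`` yields an :class:`EpithelialMask`;
    anything else yields a :class:`LabelMask`.
    """
    raster_path = Path(raster_path)
    if not raster_path.exists():
        raise FileNotFoundError(str(raster_path))
    legend = read_legend(legend_path)
    if raster_path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(raster_path)
    else:
        data = iio.imread(raster_path)
    if data.ndim != 2:
        raise FormatError(f"{raster_path} is not a single-channel mask")
    bad = np.setdiff1d(np.unique(data), np.array(sorted(legend)))
    if bad.size:
        raise FormatError(
            f"{raster_path} contains values absent from the legend: {bad.tolist()}"
        )
    if set(legend) == {0, 1}:
        return EpithelialMask(data=data.astype(np.uint8))
    return LabelMask(data=data.astype(np.int64), legend=legend)


def write_mask(mask, raster_path, legend_path) -> Path:
    raster_path = Path(raster_path)
    legend = getattr(mask, "legend", BINARY_LEGEND)
    data = np.asarray(mask.data).astype(np.uint8)
    if raster_path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(raster_path, data)
    else:
        iio.imwrite(raster_path, data)
    write_legend(legend, legend_path)
    return raster_path


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def read_manifest(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path, dtype={"core_id": str, "patient_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest {path} lacks columns {missing}")
    return df


def write_manifest(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest lacks columns {missing}")
    df.to_csv(path, index=False)
    return path
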