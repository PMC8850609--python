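"""Shared image/annotation data types, file I/O and the IoU metric.

Coordinate convention used across the whole package: 0-based ``(row, col)``,
origin at the top-left corner, row-major arrays.  Bounding boxes are
half-open in both axes: ``(min_row, min_col, height, width)`` covers rows
``min_row .. min_row+height-1``.

Visible-spectrum images are 8-bit RGB on disk and ``float`` in ``[0, 1]`` in
memory.  Thermal images hold per-pixel skin temperature in degrees Celsius
(float32 single-channel TIFF on disk, CSV grid accepted as a fixture
fallback).  A visible/thermal pair acquired at the same instant is
pixel-correlated: same height and width, same scene geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np


class Series(str, Enum):
    """Acquisition time point: before or ~15 min after allergen application."""

    PRE = "pre"
    POST = "post"


class MarkerShape(str, Enum):
    CIRCLE = "circle"
    SQUARE = "square"  # histamine positive-control site


class Provenance(str, Enum):
    DETECTED = "detected"
    INFERRED = "inferred"


@dataclass
class VisibleImage:
    """3-channel skin photograph; pixels float in [0, 1]."""

    pixels: np.ndarray  # (H, W, 3)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"visible image must be HxWx3, got {self.pixels.shape}")
        if self.pixels.shape[0] <= 0 or self.pixels.shape[1] <= 0:
            raise ValueError("empty visible image")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("visible image contains non-finite values")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class ThermalImage:
    """Single-channel temperature map in degrees Celsius."""

    pixels: np.ndarray  # (H, W)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"thermal image must be HxW, got {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("thermal image contains non-finite values")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class ImageBundle:
    """Pixel-correlated visible + thermal pair at one time point."""

    visible: VisibleImage
    thermal: ThermalImage
    series: Series = Series.PRE

    def __post_init__(self) -> None:
        if isinstance(self.series, str):
            self.series = Series(self.series)
        if (self.visible.height, self.visible.width) != (
            self.thermal.height,
            self.thermal.width,
        ):
            raise CorrelationError(
                "visible and thermal shapes differ: "
                f"{(self.visible.height, self.visible.width)} vs "
                f"{(self.thermal.height, self.thermal.width)}"
            )

    @property
    def shape(self) -> Tuple[int, int]:
        return self.visible.height, self.visible.width


class CorrelationError(ValueError):
    """Visible and thermal images of one bundle do not share a pixel grid."""


@dataclass
class MarkerAnnotation:
    """Manually marked application site.

    ``injection_point`` is where the lancet pierced the skin;
    ``marker_point`` is any point on the highlighter circle drawn around it.
    Their distance defines the radius of the ground-truth mask disc.
    """

    injection_point: Tuple[float, float]  # (row, col)
    marker_point: Tuple[float, float]  # (row, col)
    shape: MarkerShape = MarkerShape.CIRCLE
    site_id: str = ""

    def __post_init__(self) -> None:
        if isinstance(self.shape, str):
            self.shape = MarkerShape(self.shape)
        if tuple(self.injection_point) == tuple(self.marker_point):
            raise ValueError("marker_point must differ from injection_point")

    @property
    def radius(self) -> float:
        dr = self.injection_point[0] - self.marker_point[0]
        dc = self.injection_point[1] - self.marker_point[1]
        return float(np.hypot(dr, dc))


@dataclass
class Segment:
    """A detected or inferred allergen application area."""

    center: Tuple[float, float]  # (row, col)
    bbox: Tuple[float, float, float, float]  # (min_row, min_col, height, width)
    grid_index: Optional[Tuple[int, int]] = None  # (line in {0,1}, position 0..3)
    provenance: Provenance = Provenance.DETECTED

    def __post_init__(self) -> None:
        if isinstance(self.provenance, str):
            self.provenance = Provenance(self.provenance)
        r0, c0, h, w = self.bbox
        if h <= 0 or w <= 0:
            raise ValueError("bbox extents must be positive")
        r, c = self.center
        if not (r0 <= r <= r0 + h and c0 <= c <= c0 + w):
            raise ValueError("bbox must contain center")


@dataclass
class PatientRecord:
    """Interview attributes recorded at the start of the examination."""

    patient_id: str
    sex: str  # "M" or "F"
    age: float  # years
    weight: float  # kg
    height: float  # cm
    body_temperature: float  # degrees C

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.age <= 0 or self.weight <= 0:
            raise ValueError("age and weight must be positive")
        if not 30.0 < self.body_temperature < 45.0:
            raise ValueError("body temperature outside plausible (30, 45) C range")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_visible(path: str | Path) -> VisibleImage:
    """Read an 8-bit RGB PNG/TIFF; values rescaled to [0, 1]."""
    import imageio.v3 as iio

    arr = iio.imread(Path(path))
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise IOError(f"{path}: expected 3-channel image, got shape {arr.shape}")
    return VisibleImage(arr.astype(np.float64) / 255.0)


def write_visible(path: str | Path, image: VisibleImage) -> None:
    import imageio.v3 as iio

    arr = np.clip(np.rint(image.pixels * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), arr)


def read_thermal(path: str | Path) -> ThermalImage:
    """Read a float32 single-channel TIFF (degrees C) or a CSV grid.

    Values are passed through unscaled: the file already holds Celsius.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    elif path.suffix.lower() == ".csv":
        arr = np.loadtxt(path, delimiter=",", dtype=np.float64)
    else:
        raise IOError(f"{path}: unsupported thermal format {path.suffix!r}")
    if arr.ndim != 2:
        raise IOError(f"{path}: thermal image must be single-channel, got {arr.shape}")
    return ThermalImage(arr.astype(np.float64))


def write_thermal(path: str | Path, image: ThermalImage) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, image.pixels.astype(np.float32))
    elif path.suffix.lower() == ".csv":
        np.savetxt(path, image.pixels, delimiter=",", fmt="%.6f")
    else:
        raise IOError(f"{path}: unsupported thermal format {path.suffix!r}")


def read_bundle(
    visible_path: str | Path,
    thermal_path: str | Path,
    series: Series | str = Series.PRE,
) -> ImageBundle:
    """Load a pixel-correlated visible/thermal pair.

    Raises :class:`CorrelationError` if the two files disagree in shape.
    """
    visible = read_visible(visible_path)
    thermal = read_thermal(thermal_path)
    return ImageBundle(visible=visible, thermal=thermal, series=Series(series))


def write_bundle(
    directory: str | Path, stem: str, bundle: ImageBundle
) -> Tuple[Path, Path]:
    """Write ``<stem>_visible.png`` and ``<stem>_thermal.tif`` into *directory*."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    vpath = directory / f"{stem}_visible.png"
    tpath = directory / f"{stem}_thermal.tif"
    write_visible(vpath, bundle.visible)
    write_thermal(tpath, bundle.thermal)
    return vpath, tpath


def read_annotations(path: str | Path) -> list[MarkerAnnotation]:
    """Read per-image marker annotations from JSON."""
    data = json.loads(Path(path).read_text())
    return [
        MarkerAnnotation(
            injection_point=tuple(d["injection_point"]),
            marker_point=tuple(d["marker_point"]),
            shape=MarkerShape(d.get("shape", "circle")),
            site_id=d.get("site_id", ""),
        )
        for d in data
    ]


def write_annotations(path: str | Path, annotations: Sequence[MarkerAnnotation]) -> None:
    data = [
        {
            "site_id": a.site_id,
            "shape": a.shape.value,
            "injection_point": list(map(float, a.injection_point)),
            "marker_point": list(map(float, a.marker_point)),
        }
        for a in annotations
    ]
    Path(path).write_text(json.dumps(data, indent=1))


# ---------------------------------------------------------------------------
# Metric
# ---------------------------------------------------------------------------

def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection over union of two binary masks.

    Defined as 1.0 when both masks are empty (identity semantics for the
    degenerate case).
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError(f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}")
    union = np.count_nonzero(mask_a | mask_b)
    if union == 0:
        return 1.0
    inter = np.count_nonzero(mask_a & mask_b)
    return inter / union
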