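"""Image and tabular I/O plus the coordinate and intensity conventions.

Conventions used throughout the package:

* pixel coordinates are ``(row, col)`` with the origin at the top-left
  corner and 0-based indexing; object centers are real-valued and refer
  to pixel centers;
* stored images are single-plane 16-bit grayscale (TIFF; PNG is accepted
  read-only for fixtures); in memory they are processed as floats;
* the sample-plane pixel size defaults to 0.1625 µm — a 6.5 µm camera
  pixel behind a 40x objective — and is carried as metadata, never read
  from file tags.
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "DEFAULT_PIXEL_SIZE_UM",
    "Image",
    "ImagingGeometry",
    "Roi",
    "RoiSet",
    "read_image",
    "write_image",
    "write_detections",
    "read_detections",
    "write_rois",
    "read_rois",
    "channel_volume",
]

#: Camera pixel pitch divided by objective magnification: 6.5 µm / 40.
DEFAULT_PIXEL_SIZE_UM = 6.5 / 40.0

MAX_INTENSITY = 65535


@dataclass
class ImagingGeometry:
    """Acquisition geometry of the brightfield/fluorescence scan."""

    camera_pixel_um: float = 6.5
    magnification: float = 40.0
    view_px: tuple[int, int] = (2048, 2048)
    images_per_set: int = 30

    def __post_init__(self) -> None:
        if self.camera_pixel_um <= 0 or self.magnification <= 0:
            raise ValueError("camera pixel and magnification must be positive")
        if any(v <= 0 for v in self.view_px) or self.images_per_set <= 0:
            raise ValueError("view size and images per set must be positive")

    @property
    def pixel_size_um(self) -> float:
        """Sample-plane pixel size (µm)."""
        return self.camera_pixel_um / self.magnification


@dataclass
class Image:
    """A single-plane grayscale image with physical pixel size."""

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    name: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"image must be 2-D with positive size, got shape {px.shape}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if np.any(px < 0) or np.any(px > MAX_INTENSITY):
            raise ValueError("intensities must lie in [0, 65535]")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class Roi:
    x_px: float
    y_px: float
    radius_px: float
    label: str = ""


@dataclass
class RoiSet:
    """Disc ROIs shared between a brightfield tile and its fluorescence pair.

    ``x_px`` is the column and ``y_px`` the row of the disc center.
    """

    rois: list[Roi] = field(default_factory=list)
    source_image: str = ""

    def __len__(self) -> int:
        return len(self.rois)

    def validate_against(self, shape: tuple[int, int]) -> None:
        h, w = shape
        for roi in self.rois:
            if not (0 <= roi.y_px < h and 0 <= roi.x_px < w):
                raise ValueError(f"ROI center ({roi.x_px}, {roi.y_px}) outside image {shape}")
            if roi.radius_px <= 0:
                raise ValueError("ROI radius must be positive")


def read_image(path: str | os.PathLike, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> Image:
    """Read a single-plane grayscale TIFF (or PNG fixture) bit-exactly.

    The physical pixel size comes from configuration, not from file
    metadata. Multi-channel input is rejected with the offending shape.
    """
    path = os.fspath(path)
    if path.lower().endswith((".png",)):
        import imageio.v3 as iio

        arr = iio.imread(path)
    else:
        arr = tifffile.imread(path)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(
            f"expected a single-plane grayscale image, got shape {arr.shape} from {path!r}"
        )
    return Image(pixels=arr, pixel_size_um=pixel_size_um, name=os.path.basename(path))


def write_image(image: Image, path: str | os.PathLike) -> None:
    """Write as 16-bit single-plane TIFF (bit-exact for uint16 input)."""
    px = image.pixels
    if not np.issubdtype(px.dtype, np.integer):
        px = np.clip(np.rint(px), 0, MAX_INTENSITY)
    tifffile.imwrite(os.fspath(path), px.astype(np.uint16))


_DETECTION_FIELDS = ("image", "x_px", "y_px", "radius_px", "class", "score")


def write_detections(candidates: Sequence, path: str | os.PathLike) -> None:
    """Write detections as CSV with header (image, x_px, y_px, radius_px, class, score).

    Accepts any objects exposing ``center`` (row, col), ``radius_px``,
    ``peak_score`` and optional ``label``/``source`` attributes —
    in practice :class:`carfind.prefilter.Candidate`.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_DETECTION_FIELDS)
        for cand in candidates:
            row, col = cand.center
            label = getattr(cand, "label", None) or "unclassified"
            image = getattr(cand, "source", "") or ""
            writer.writerow([image, repr(float(col)), repr(float(row)),
                             repr(float(cand.radius_px)), label, repr(float(cand.peak_score))])


def read_detections(path: str | os.PathLike) -> list[dict]:
    """Read a detections CSV back into a list of plain records."""
    out: list[dict] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != _DETECTION_FIELDS:
            raise ValueError(f"unexpected detections header: {reader.fieldnames}")
        for rec in reader:
            out.append(
                {
                    "image": rec["image"],
                    "x_px": float(rec["x_px"]),
                    "y_px": float(rec["y_px"]),
                    "radius_px": float(rec["radius_px"]),
                    "class": rec["class"],
                    "score": float(rec["score"]),
                }
            )
    return out


def write_rois(rois: RoiSet, path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(("image", "x_px", "y_px", "radius_px", "label"))
        for roi in rois.rois:
            writer.writerow([rois.source_image, repr(float(roi.x_px)), repr(float(roi.y_px)),
                             repr(float(roi.radius_px)), roi.label])


def read_rois(path: str | os.PathLike) -> RoiSet:
    rois: list[Roi] = []
    source = ""
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            source = rec.get("image", source)
            rois.append(Roi(float(rec["x_px"]), float(rec["y_px"]),
                            float(rec["radius_px"]), rec.get("label", "")))
    return RoiSet(rois=rois, source_image=source)


def channel_volume(height_um: float, width_mm: float, length_mm: float) -> float:
    """Rectangular flow-channel volume in µL, to 2 significant figures.

    The reference channel (203 µm x 1.0 mm x 35 mm) holds 7.1 µL.
    """
    if height_um <= 0 or width_mm <= 0 or length_mm <= 0:
        raise ValueError("all channel dimensions must be positive")
    volume_ul = (height_um * 1e-3) * width_mm * length_mm  # mm^3 == µL
    if volume_ul == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(volume_ul)))
    factor = 10.0 ** (exponent - 1)
    # re-parse to strip float artifacts of the factor multiplication
    return float(f"{round(volume_ul / factor) * factor:.12g}")


def candidate_to_record(cand) -> dict:
    """Flatten a candidate into the detections-CSV record schema."""
    row, col = cand.center
    return {
        "image": getattr(cand, "source", "") or "",
        "x_px": float(col),
        "y_px": float(row),
        "radius_px": float(cand.radius_px),
        "class": getattr(cand, "label", None) or "unclassified",
        "score": float(cand.peak_score),
    }
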