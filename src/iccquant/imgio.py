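"""Raster image I/O with physical-resolution metadata, YOLO-OBB labels
and JSON/CSV report writing.

Physical pixel size is carried in micrometres per pixel.  For TIFF it is
derived from the standard ``XResolution``/``YResolution``/
``ResolutionUnit`` tags (inch = 25400 um, centimetre = 10000 um); for
PNG/JPEG the caller must supply it.  Densities in mm^-2 assume square
pixels, so anisotropic TIFF resolutions (X and Y differing by more than
1%) are refused unless an explicit override is given.

Annotations use the YOLO oriented-bounding-box dialect: one object per
line, ``class x1 y1 x2 y2 x3 y3 x4 y4`` with corner coordinates
normalised to image width/height.
"""

from __future__ import annotations

import csv
import json
import logging
import math
import os
from dataclasses import dataclass, field
from fractions import Fraction
from typing import List, Optional, Sequence

import numpy as np
import tifffile
from PIL import Image

from .errors import ValidationError
from .geometry import OrientedBox, box_from_corners

__all__ = [
    "RasterImage",
    "read_image",
    "write_image",
    "read_labels",
    "write_labels",
    "write_report",
]

log = logging.getLogger(__name__)

_UM_PER_INCH = 25400.0
_UM_PER_CM = 10000.0


@dataclass
class RasterImage:
    """An RGB raster with optional physical pixel size.

    ``pixels`` is H x W x 3, integer intensities in [0, 255];
    ``pixel_size_um`` is micrometres per pixel (square pixels assumed).
    """

    pixels: np.ndarray
    pixel_size_um: Optional[float] = None
    source_path: Optional[str] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError(
                f"pixels must be H x W x 3, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError("image must be at least 1 x 1")
        if self.pixel_size_um is not None and not self.pixel_size_um > 0:
            raise ValidationError(
                f"pixel_size_um must be positive, got {self.pixel_size_um}")
        self.pixels = px

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


def _pixel_size_from_tiff(page: "tifffile.TiffPage") -> Optional[float]:
    tags = page.tags
    if "XResolution" not in tags or "ResolutionUnit" not in tags:
        return None
    unit = tags["ResolutionUnit"].value
    unit = int(unit) if not isinstance(unit, int) else unit
    if unit == 2:
        unit_um = _UM_PER_INCH
    elif unit == 3:
        unit_um = _UM_PER_CM
    else:  # RESUNIT.NONE or unknown: resolution is not physical
        return None

    def _ratio(v) -> float:
        if isinstance(v, tuple):
            num, den = v
            return num / den if den else 0.0
        return float(v)

    xres = _ratio(tags["XResolution"].value)
    if xres <= 0:
        return None
    if "YResolution" in tags:
        yres = _ratio(tags["YResolution"].value)
        if yres > 0 and abs(xres - yres) / max(xres, yres) > 0.01:
            raise ValidationError(
                "anisotropic TIFF resolution (X and Y differ by > 1%); "
                "supply an explicit pixel size override")
    return unit_um / xres


def read_image(path: str, pixel_size_override: Optional[float] = None) -> RasterImage:
    """Read a TIFF/PNG/JPEG image as RGB with physical pixel size.

    ``pixel_size_override`` (um/px) takes precedence over any TIFF
    resolution metadata; PNG/JPEG carry no trusted physical resolution,
    so without an override their pixel size is absent.
    """
    if pixel_size_override is not None and not pixel_size_override > 0:
        raise ValidationError(
            f"pixel size override must be positive, got {pixel_size_override}")
    if not os.path.exists(path):
        raise IOError(f"no such image file: {path}")
    ext = os.path.splitext(path)[1].lower()
    pixel_size: Optional[float] = None
    if ext in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            arr = page.asarray()
            if pixel_size_override is None:
                pixel_size = _pixel_size_from_tiff(page)
    else:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"))
    if arr.ndim == 2:  # greyscale TIFF: replicate to RGB
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim == 3 and arr.shape[2] > 3:
        arr = arr[:, :, :3]
    if pixel_size_override is not None:
        pixel_size = float(pixel_size_override)
    return RasterImage(np.ascontiguousarray(arr), pixel_size, source_path=str(path))


def write_image(image: RasterImage, path: str) -> None:
    """Write an image; TIFF output embeds resolution tags in px/cm."""
    ext = os.path.splitext(path)[1].lower()
    arr = np.asarray(image.pixels, dtype=np.uint8)
    if ext in (".tif", ".tiff"):
        kwargs = {}
        if image.pixel_size_um is not None:
            res = Fraction(_UM_PER_CM / image.pixel_size_um).limit_denominator(10**6)
            kwargs = {
                "resolution": ((res.numerator, res.denominator),
                               (res.numerator, res.denominator)),
                "resolutionunit": 3,
            }
        tifffile.imwrite(path, arr, photometric="rgb", **kwargs)
    else:
        Image.fromarray(arr).save(path)


def read_labels(path: str, image_w: int, image_h: int) -> List[OrientedBox]:
    """Parse a YOLO-OBB label file into de-normalised oriented boxes.

    Each line is ``class x1 y1 ... x4 y4`` with coordinates in [0, 1];
    corners are scaled by image width/height and converted to canonical
    boxes.  Ground-truth files carry 9 tokens (score taken as 1.0);
    prediction files may append a 10th token, the confidence in [0, 1].
    """
    if image_w <= 0 or image_h <= 0:
        raise ValidationError("image dimensions must be positive")
    boxes: List[OrientedBox] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) not in (9, 10):
                raise ValidationError(
                    f"{path}:{lineno}: expected 9 tokens (class + 8 "
                    f"coordinates, optional confidence), got {len(tokens)}")
            try:
                class_id = int(tokens[0])
                coords = [float(t) for t in tokens[1:9]]
                score = float(tokens[9]) if len(tokens) == 10 else 1.0
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            if class_id < 0:
                raise ValidationError(f"{path}:{lineno}: negative class id")
            if any(c < 0.0 or c > 1.0 for c in coords):
                raise ValidationError(
                    f"{path}:{lineno}: normalised coordinate outside [0, 1]")
            if not (0.0 <= score <= 1.0):
                raise ValidationError(
                    f"{path}:{lineno}: confidence outside [0, 1]")
            corners = np.array(coords, dtype=float).reshape(4, 2)
            corners[:, 0] *= image_w
            corners[:, 1] *= image_h
            boxes.append(box_from_corners(corners, score=score, class_id=class_id))
    return boxes


def write_labels(
    boxes: Sequence[OrientedBox], image_w: int, image_h: int, path: str,
    scores: bool = False,
) -> None:
    """Write boxes as normalised YOLO-OBB lines, in input order.

    Corners falling outside the image are clamped to the border at write
    time (in-memory boxes stay unclamped); clamping is reported via the
    module logger.  With ``scores=True`` each line gets a trailing
    confidence token (prediction files).
    """
    if image_w <= 0 or image_h <= 0:
        raise ValidationError("image dimensions must be positive")
    lines = []
    n_clamped = 0
    for b in boxes:
        corners = b.corners()
        norm = corners / np.array([image_w, image_h], dtype=float)
        if (norm < 0).any() or (norm > 1).any():
            n_clamped += 1
            norm = np.clip(norm, 0.0, 1.0)
        flat = " ".join(f"{v:.8f}" for v in norm.ravel())
        line = f"{b.class_id} {flat}"
        if scores:
            line += f" {b.score:.6f}"
        lines.append(line)
    if n_clamped:
        log.warning("write_labels: clamped %d box(es) to the image border in %s",
                    n_clamped, path)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def _check_finite(obj, ctx: str) -> None:
    if isinstance(obj, dict):
        for k, v in obj.items():
            _check_finite(v, f"{ctx}.{k}")
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            _check_finite(v, f"{ctx}[{i}]")
    elif isinstance(obj, float) and not math.isfinite(obj):
        raise ValidationError(f"non-finite report field: {ctx}")


def write_report(reports, json_path: Optional[str] = None,
                 csv_path: Optional[str] = None) -> None:
    """Write one or more report dicts as JSON (full nesting) and CSV
    (one row per slide, scalar fields only)."""
    if isinstance(reports, dict):
        reports = [reports]
    reports = [r.to_dict() if hasattr(r, "to_dict") else dict(r) for r in reports]
    for r in reports:
        _check_finite(r, "report")
    if json_path:
        payload = reports[0] if len(reports) == 1 else reports
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
    if csv_path:
        scalar_rows = []
        for r in reports:
            row = {}
            for k, v in r.items():
                if isinstance(v, (list, tuple)) and len(v) == 2 and all(
                        isinstance(x, (int, float)) for x in v):
                    row[f"{k}_lo"], row[f"{k}_hi"] = v
                elif isinstance(v, (str, int, float, bool)) or v is None:
                    row[k] = v
            scalar_rows.append(row)
        fields: List[str] = []
        for row in scalar_rows:
            for k in row:
                if k not in fields:
                    fields.append(k)
        with open(csv_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fields)
            writer.writeheader()
            writer.writerows(scalar_rows)
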