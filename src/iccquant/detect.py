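"""Detector contract and the classical DAB-blob baseline.

The pipeline treats the detector as a pluggable contract: any callable
object with ``detect(image) -> list[OrientedBox]`` (tile-local
coordinates, canonical boxes, scores in [0, 1]).  A trained neural
detector can be registered under a name and wrapped; the built-in
``classical`` baseline keeps the package self-contained and
deterministic:

1. H-DAB stain separation in optical-density space (Ruifrok–Johnston
   basis), giving a DAB-brown OD map;
2. thresholding + morphological opening + connected components with
   area and elongation filters;
3. oriented-box fitting from second-order moments, scored by mean DAB
   OD within the component.

Optical density is ``-log10((I + 1) / 256)`` per channel; stain
concentrations are the projection of the OD vector onto the stain basis
(3x3 inverse, negative loadings clipped to zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Union

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk, opening

from .errors import ValidationError
from .geometry import OrientedBox, canonicalize
from .imgio import RasterImage

__all__ = [
    "HDAB_BASIS",
    "DetectorParams",
    "StainChannels",
    "Component",
    "separate_stains",
    "rgb_from_stains",
    "extract_components",
    "fit_oriented_box",
    "score_component",
    "ClassicalDetector",
    "get_detector",
    "register_detector",
]

# Ruifrok & Johnston H-DAB stain vectors (rows: haematoxylin, DAB,
# orthogonal residual), unit-normalised.  Overridable per detector.
_H = np.array([0.65, 0.70, 0.29])
_D = np.array([0.27, 0.57, 0.78])
_R = np.cross(_H, _D)
HDAB_BASIS = np.stack([
    _H / np.linalg.norm(_H),
    _D / np.linalg.norm(_D),
    _R / np.linalg.norm(_R),
])


@dataclass(frozen=True)
class DetectorParams:
    """Tunables of the classical baseline.

    Defaults were chosen on the synthetic generator (they are not taken
    from any published protocol): DAB OD threshold 0.15, component area
    in [30, 5000] px, opening radius 1 px, elongation >= 1.2 (ICCs are
    spindle-shaped; round nuclei are rejected).
    """

    dab_od_thresh: float = 0.15
    min_area_px: int = 30
    max_area_px: int = 5000
    min_elongation: float = 1.2
    open_radius_px: int = 1

    def __post_init__(self) -> None:
        if self.dab_od_thresh < 0:
            raise ValidationError("dab_od_thresh must be >= 0")
        if not (0 <= self.min_area_px < self.max_area_px):
            raise ValidationError("need 0 <= min_area_px < max_area_px")
        if self.min_elongation < 1.0:
            raise ValidationError("min_elongation must be >= 1")
        if self.open_radius_px < 0:
            raise ValidationError("open_radius_px must be >= 0")


@dataclass
class StainChannels:
    """Per-pixel optical-density maps for the two stains."""

    haematoxylin_od: np.ndarray
    dab_od: np.ndarray


@dataclass
class Component:
    """A connected DAB-positive pixel component, as (row, col) coords."""

    coords: np.ndarray  # (N, 2) int array of (row, col)

    @property
    def area(self) -> int:
        return int(len(self.coords))


def _as_rgb_array(image: Union[RasterImage, np.ndarray]) -> np.ndarray:
    arr = image.pixels if isinstance(image, RasterImage) else np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValidationError(f"expected H x W x 3 image, got shape {arr.shape}")
    return arr.astype(float)


def separate_stains(
    image: Union[RasterImage, np.ndarray],
    basis: np.ndarray = HDAB_BASIS,
) -> StainChannels:
    """Unmix an RGB image into haematoxylin and DAB OD maps.

    Accepts a :class:`RasterImage` or a raw H x W x 3 array (float
    intensities are used as-is, which keeps the unmixing exactly
    inverse to :func:`rgb_from_stains`).
    """
    arr = _as_rgb_array(image)
    od = -np.log10((arr + 1.0) / 256.0)
    conc = od @ np.linalg.inv(basis)
    conc = np.clip(conc, 0.0, None)
    return StainChannels(haematoxylin_od=conc[..., 0], dab_od=conc[..., 1])


def rgb_from_stains(
    h_od: np.ndarray,
    dab_od: np.ndarray,
    basis: np.ndarray = HDAB_BASIS,
    quantize: bool = True,
) -> np.ndarray:
    """Render RGB intensities from stain OD maps (inverse of
    :func:`separate_stains`); used by the synthetic generator."""
    od = (np.stack([h_od, dab_od, np.zeros_like(h_od)], axis=-1) @ basis)
    rgb = 256.0 * np.power(10.0, -od) - 1.0
    rgb = np.clip(rgb, 0.0, 255.0)
    if quantize:
        rgb = np.rint(rgb).astype(np.uint8)
    return rgb


def extract_components(
    dab_od: np.ndarray, params: DetectorParams
) -> List[Component]:
    """DAB-positive connected components after opening and shape filters.

    Threshold at ``dab_od_thresh``, open with a disk of
    ``open_radius_px``, label 8-connected components, then keep those
    with area in ``[min_area_px, max_area_px]`` and elongation (major /
    minor axis length from second moments) >= ``min_elongation``.
    """
    mask = np.asarray(dab_od) >= params.dab_od_thresh
    if params.open_radius_px > 0:
        mask = opening(mask, disk(params.open_radius_px))
    labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    out: List[Component] = []
    if n == 0:
        return out
    objects = ndi.find_objects(labels)
    for idx, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        sub = labels[sl] == idx
        area = int(sub.sum())
        if area < params.min_area_px or area > params.max_area_px:
            continue
        rows, cols = np.nonzero(sub)
        coords = np.column_stack([rows + sl[0].start, cols + sl[1].start])
        if _elongation(coords) < params.min_elongation:
            continue
        out.append(Component(coords=coords))
    return out


def _second_moments(coords: np.ndarray):
    ys = coords[:, 0].astype(float)
    xs = coords[:, 1].astype(float)
    mx, my = xs.mean(), ys.mean()
    dx, dy = xs - mx, ys - my
    # +1/12: variance of the unit-square pixel footprint
    mu20 = dx @ dx / len(xs) + 1.0 / 12.0
    mu02 = dy @ dy / len(ys) + 1.0 / 12.0
    mu11 = dx @ dy / len(xs)
    return mx, my, mu20, mu02, mu11


def _elongation(coords: np.ndarray) -> float:
    _, _, mu20, mu02, mu11 = _second_moments(coords)
    common = math.hypot(mu20 - mu02, 2.0 * mu11)
    lam1 = (mu20 + mu02 + common) / 2.0
    lam2 = (mu20 + mu02 - common) / 2.0
    if lam2 <= 0:
        return math.inf
    return math.sqrt(lam1 / lam2)


def fit_oriented_box(component: Union[Component, np.ndarray]) -> OrientedBox:
    """Fit an oriented box to a pixel component.

    Orientation comes from the principal axis of the second-order
    central moments; side lengths from the pixel extent projected onto
    the principal axes (+1 px for the pixel footprint).  Accepts a
    :class:`Component`, an (N, 2) coordinate array, or a boolean mask.
    Collinear components fall back to an axis-aligned box.
    """
    if isinstance(component, Component):
        coords = component.coords
    else:
        arr = np.asarray(component)
        if arr.ndim == 2 and arr.shape[1] == 2 and arr.dtype != bool:
            coords = arr
        else:
            coords = np.column_stack(np.nonzero(arr))
    if len(coords) < 3:
        raise ValidationError("component must have at least 3 pixels")
    mx, my, mu20, mu02, mu11 = _second_moments(coords)
    if abs(mu11) < 1e-12 and abs(mu20 - mu02) < 1e-12:
        theta = 0.0
    else:
        theta = 0.5 * math.atan2(2.0 * mu11, mu20 - mu02)
    c, s = math.cos(theta), math.sin(theta)
    xs = coords[:, 1].astype(float) - mx
    ys = coords[:, 0].astype(float) - my
    u = xs * c + ys * s
    v = -xs * s + ys * c
    w = float(u.max() - u.min()) + 1.0
    h = float(v.max() - v.min()) + 1.0
    # centre of the fitted extent, mapped back to image coordinates
    uc, vc = (u.max() + u.min()) / 2.0, (v.max() + v.min()) / 2.0
    cx = mx + uc * c - vc * s + 0.5
    cy = my + uc * s + vc * c + 0.5
    return canonicalize(cx, cy, w, h, theta)


def score_component(
    component: Union[Component, np.ndarray],
    dab_od: np.ndarray,
    od_saturation: float = 1.0,
) -> float:
    """Confidence from mean DAB OD inside the component, clipped to
    [0, 1] at ``od_saturation`` (monotone in mean OD)."""
    coords = component.coords if isinstance(component, Component) else np.asarray(component)
    if len(coords) == 0:
        raise ValidationError("component must be non-empty")
    mean_od = float(np.asarray(dab_od)[coords[:, 0], coords[:, 1]].mean())
    return float(np.clip(mean_od / od_saturation, 0.0, 1.0))


class ClassicalDetector:
    """Deterministic DAB-blob detector implementing the pipeline contract."""

    def __init__(self, params: Optional[DetectorParams] = None,
                 basis: np.ndarray = HDAB_BASIS):
        self.params = params or DetectorParams()
        self.basis = basis

    def detect(self, image: Union[RasterImage, np.ndarray]) -> List[OrientedBox]:
        stains = separate_stains(image, self.basis)
        boxes: List[OrientedBox] = []
        for comp in extract_components(stains.dab_od, self.params):
            box = fit_oriented_box(comp)
            score = score_component(comp, stains.dab_od)
            boxes.append(canonicalize(box.cx, box.cy, box.w, box.h, box.theta,
                                      score=score))
        return boxes

    def __call__(self, image) -> List[OrientedBox]:
        return self.detect(image)


_REGISTRY: Dict[str, Callable[..., object]] = {"classical": ClassicalDetector}


def register_detector(name: str, factory: Callable[..., object]) -> None:
    """Register a detector factory discoverable by name in configs."""
    _REGISTRY[name] = factory


def get_detector(name: str, **kwargs):
    """Instantiate a registered detector (``classical`` is built in)."""
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise ValidationError(
            f"unknown detector {name!r}; registered: {sorted(_REGISTRY)}")
    return factory(**kwargs)
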