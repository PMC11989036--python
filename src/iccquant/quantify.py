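"""Tissue masking, area conversion, ICC density and the ANO1 score.

Tissue is separated from bare glass by colour saturation: stained
tissue is chromatic while glass is near-achromatic white, so
``saturation = (max(RGB) - min(RGB)) / max(RGB)`` thresholded at a small
value, followed by morphological cleanup (closing, opening, hole
filling, small-object removal), yields a binary tissue mask.  Areas are
converted with ``area_mm2 = n_pixels * pixel_size_um^2 / 1e6`` (square
pixels), and ICC density is reported per mm^2 of tissue, not per slide.

For a batch of slides the mean density gets a Student-t confidence
interval; the semiquantitative ANO1 membrane-expression score bins the
positive fraction as 0 (negative), 1 (up to 10%), 2 (over 10% up to
50%), 3 (over 50%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage as ndi
from scipy import stats
from skimage.morphology import closing, disk, opening

from .errors import ValidationError
from .imgio import RasterImage

__all__ = [
    "TissueMask",
    "DensityReport",
    "Ano1Score",
    "tissue_mask",
    "area_mm2",
    "density",
    "mean_density_ci",
    "ano1_score",
]


@dataclass
class TissueMask:
    mask: np.ndarray  # binary H x W
    tissue_fraction: float

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class DensityReport:
    """Per-slide quantification result.

    ``density_per_mm2`` is None when the tissue area is zero (and there
    are no cells); ``mean_density_ci`` is filled only in batch mode.
    """

    n_cells: int
    tissue_area_mm2: float
    density_per_mm2: Optional[float]
    conf_thresh_used: float
    mean_density_ci: Optional[Tuple[float, float]] = None
    slide: Optional[str] = None

    def to_dict(self) -> dict:
        d = {
            "n_cells": self.n_cells,
            "tissue_area_mm2": self.tissue_area_mm2,
            "density_per_mm2": self.density_per_mm2,
            "conf_thresh_used": self.conf_thresh_used,
        }
        if self.slide is not None:
            d["slide"] = self.slide
        if self.mean_density_ci is not None:
            d["mean_density_ci"] = list(self.mean_density_ci)
        return d


@dataclass(frozen=True)
class Ano1Score:
    value: int


def tissue_mask(
    image: Union[RasterImage, np.ndarray],
    sat_thresh: float = 0.08,
    close_radius_px: int = 5,
    open_radius_px: int = 3,
    min_object_px: int = 10_000,
) -> TissueMask:
    """Binary tissue mask from colour saturation plus morphology.

    All thresholds are exposed: the defaults suit ~0.25-1 um/px
    brightfield scans where glass is near-white.
    """
    arr = image.pixels if isinstance(image, RasterImage) else np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValidationError(f"expected H x W x 3 image, got shape {arr.shape}")
    arr = arr.astype(float)
    cmax = arr.max(axis=2)
    cmin = arr.min(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        sat = np.where(cmax > 0, (cmax - cmin) / cmax, 0.0)
    mask = sat >= sat_thresh
    if close_radius_px > 0:
        mask = closing(mask, disk(close_radius_px))
    if open_radius_px > 0:
        mask = opening(mask, disk(open_radius_px))
    mask = ndi.binary_fill_holes(mask)
    if min_object_px > 1:
        labels, n = ndi.label(mask)
        if n:
            sizes = np.bincount(labels.ravel())
            small = np.flatnonzero(sizes < min_object_px)
            mask &= ~np.isin(labels, small[small > 0])
    frac = float(mask.sum()) / mask.size
    return TissueMask(mask=mask, tissue_fraction=frac)


def area_mm2(mask: Union[TissueMask, np.ndarray], pixel_size_um: Optional[float]) -> float:
    """Physical area of the mask's true pixels in mm^2."""
    if pixel_size_um is None:
        raise ValidationError(
            "pixel size is unknown; pass an explicit pixel_size_um override "
            "(physical areas are never computed from an assumed resolution)")
    if not pixel_size_um > 0:
        raise ValidationError(f"pixel_size_um must be positive, got {pixel_size_um}")
    n = mask.n_pixels if isinstance(mask, TissueMask) else int(np.asarray(mask).sum())
    return n * pixel_size_um ** 2 / 1e6


def density(n_cells: int, area: float) -> Optional[float]:
    """Cells per mm^2 of tissue; None (missing) for an empty slide."""
    if n_cells < 0:
        raise ValidationError("n_cells must be >= 0")
    if area < 0:
        raise ValidationError("area must be >= 0")
    if area == 0:
        if n_cells > 0:
            raise ValidationError(
                f"{n_cells} cells counted on zero tissue area")
        return None
    return n_cells / area


def mean_density_ci(
    densities: Sequence[float], level: float = 0.95
) -> Tuple[float, float]:
    """Student-t confidence interval for the mean of per-sample densities.

    mean +/- t_{(1+level)/2, n-1} * sd / sqrt(n); requires n >= 2.
    A zero-variance sample yields the degenerate interval (mean, mean).
    """
    x = np.asarray(densities, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValidationError("need at least 2 density values for a CI")
    if not np.isfinite(x).all():
        raise ValidationError("densities must be finite")
    if not (0.0 < level < 1.0):
        raise ValidationError("level must lie in (0, 1)")
    n = len(x)
    m = float(x.mean())
    sd = float(x.std(ddof=1))
    t = float(stats.t.ppf((1.0 + level) / 2.0, n - 1))
    hw = t * sd / np.sqrt(n)
    return (m - hw, m + hw)


def ano1_score(positive_fraction: float) -> Ano1Score:
    """Semiquantitative ANO1 membrane-expression score.

    0 for no expression, 1 for a positive fraction up to 10%, 2 for
    over 10% up to 50%, 3 for over 50%.
    """
    f = float(positive_fraction)
    if not (0.0 <= f <= 1.0):
        raise ValidationError(f"positive fraction must lie in [0, 1], got {f}")
    if f == 0.0:
        return Ano1Score(0)
    if f <= 0.10:
        return Ano1Score(1)
    if f <= 0.50:
        return Ano1Score(2)
    return Ano1Score(3)
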