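"""Synthetic CD117-IHC image generator with known oriented-box ground
truth, plus the D4 rotation/flip augmentation scheme.

The generator emulates the appearance that matters to the downstream
pipeline rather than photorealistic histology:

* a smooth random tissue blob (haematoxylin-tinted, chromatic) on a
  near-white achromatic glass background, occupying a controllable
  fraction of the frame;
* ICC-like cells: elongated DAB-brown ellipse bodies with 1-3 thin
  low-intensity processes, at uniformly random orientations, placed
  fully inside the tissue with bounded pairwise overlap;
* distractor nuclei: haematoxylin-only (blue-violet) ellipses that a
  DAB-specific detector must ignore.

Rendering goes through the same H-DAB optical-density basis that the
detector inverts, so stain-level ground truth survives the round trip.
The ground-truth oriented box encloses the cell body (the soma);
processes may extend past it.  Everything is driven by one integer
seed and is bit-reproducible.
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass, replace
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi

from .detect import rgb_from_stains
from .errors import GenerationError, ValidationError
from .geometry import OrientedBox, box_from_corners, canonicalize, obb_iou
from .imgio import RasterImage, write_image, write_labels

__all__ = [
    "SynthSpec",
    "generate_image",
    "augment",
    "AUGMENTATIONS",
    "transform_box",
    "make_dataset",
]

_MAX_PLACEMENT_ATTEMPTS = 10_000
_PLACEMENT_MAX_IOU = 0.3


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic slide.

    Defaults describe a 1024 px tile at 0.5 um/px with moderately dense,
    strongly stained cells — the regime of a well-stained CD117 slide at
    working magnification.
    """

    seed: int = 0
    width: int = 1024
    height: int = 1024
    n_cells: int = 30
    cell_len_range: Tuple[float, float] = (28.0, 55.0)
    cell_aspect_range: Tuple[float, float] = (0.28, 0.5)
    dab_intensity_range: Tuple[float, float] = (0.6, 0.9)
    n_distractors: int = 40
    tissue_fraction: float = 0.7
    pixel_size_um: float = 0.5

    def __post_init__(self) -> None:
        for name in ("cell_len_range", "cell_aspect_range", "dab_intensity_range"):
            lo, hi = getattr(self, name)
            if not (lo <= hi):
                raise ValidationError(f"{name} must satisfy low <= high")
        if self.n_cells < 0 or self.n_distractors < 0:
            raise ValidationError("counts must be >= 0")
        if not (0.0 < self.tissue_fraction <= 1.0):
            raise ValidationError("tissue_fraction must lie in (0, 1]")
        if self.width < 1 or self.height < 1:
            raise ValidationError("image must be at least 1 x 1")
        lo, hi = self.cell_aspect_range
        if not (0.0 < lo and hi <= 1.0):
            raise ValidationError("cell_aspect_range must lie in (0, 1]")


def _tissue_blob(rng: np.random.Generator, h: int, w: int, fraction: float) -> np.ndarray:
    """Smooth random blob covering exactly ``fraction`` of the pixels
    (quantile threshold of low-pass noise)."""
    if fraction >= 1.0:
        return np.ones((h, w), dtype=bool)
    noise = rng.standard_normal((h, w))
    sigma = max(min(h, w) / 10.0, 2.0)
    smooth = ndi.gaussian_filter(noise, sigma=sigma)
    thresh = np.quantile(smooth, 1.0 - fraction)
    return smooth >= thresh


def _ellipse_mask(patch_h: int, patch_w: int, cy: float, cx: float,
                  a: float, b: float, theta: float) -> np.ndarray:
    """Boolean mask of a rotated ellipse evaluated at pixel centres."""
    yy, xx = np.mgrid[0:patch_h, 0:patch_w]
    x = xx + 0.5 - cx
    y = yy + 0.5 - cy
    c, s = math.cos(theta), math.sin(theta)
    u = x * c + y * s
    v = -x * s + y * c
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


# Processes stain much fainter than the soma (thin cytoplasm transmits
# little chromogen); they are visible but stay below typical
# segmentation thresholds, so the detected blob is the soma that the
# ground-truth box encloses.
_PROCESS_OD_FRACTION = 0.15


def _cell_patch(dab_shape: Tuple[int, int], box: OrientedBox):
    """Local patch window and soma ellipse mask for one cell."""
    h, w = dab_shape
    a, b = box.w / 2.0, box.h / 2.0
    pad = int(math.ceil(box.w * 0.6)) + 4
    r0 = max(int(box.cy) - pad, 0)
    c0 = max(int(box.cx) - pad, 0)
    r1 = min(int(box.cy) + pad, h)
    c1 = min(int(box.cx) + pad, w)
    body = _ellipse_mask(r1 - r0, c1 - c0, box.cy - r0, box.cx - c0,
                         a, b, box.theta)
    return (r0, c0, r1, c1), body


def _draw_cell(dab_od: np.ndarray, rng: np.random.Generator,
               box: OrientedBox, body_od: float,
               window, body: np.ndarray) -> None:
    """Paint one cell (ellipse soma + thin faint processes) into the
    DAB map."""
    r0, c0, r1, c1 = window
    sub = dab_od[r0:r1, c0:c1]
    a = box.w / 2.0
    texture = body_od * (0.9 + 0.2 * rng.random(sub.shape))
    np.maximum(sub, np.where(body, texture, 0.0), out=sub)

    # 1-3 thin processes leaving the soma roughly along the long axis
    n_proc = rng.integers(1, 4)
    for _ in range(n_proc):
        end_sign = -1.0 if rng.random() < 0.5 else 1.0
        ang = box.theta + rng.uniform(-0.6, 0.6)
        direction = np.array([math.cos(ang), math.sin(ang)]) * end_sign
        start = np.array([box.cx - c0, box.cy - r0]) + direction * a * 0.9
        length = rng.uniform(0.15, 0.35) * box.w
        end = start + direction * length
        n_steps = max(int(length * 2), 2)
        ts = np.linspace(0.0, 1.0, n_steps)
        pts = start[None, :] + ts[:, None] * (end - start)[None, :]
        cols = np.clip(np.round(pts[:, 0]).astype(int), 0, sub.shape[1] - 1)
        rows = np.clip(np.round(pts[:, 1]).astype(int), 0, sub.shape[0] - 1)
        proc = np.zeros(sub.shape, dtype=bool)
        proc[rows, cols] = True
        proc = ndi.binary_dilation(proc, iterations=1)
        np.maximum(sub, np.where(proc, body_od * _PROCESS_OD_FRACTION, 0.0),
                   out=sub)


def generate_image(
    spec: SynthSpec,
) -> Tuple[RasterImage, List[OrientedBox], np.ndarray]:
    """Generate one synthetic slide.

    Returns the image, the ground-truth oriented boxes (score 1.0) and
    the true tissue mask.  Placement rejection-samples cell centres so
    every ground-truth box lies inside the tissue and pairwise box IoU
    stays below 0.3; an over-dense request fails with a
    :class:`GenerationError` after 10,000 attempts.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    tissue = _tissue_blob(rng, h, w, spec.tissue_fraction)

    # distance to the tissue boundary, for keeping whole boxes inside
    dist = ndi.distance_transform_edt(tissue)

    h_od = np.zeros((h, w))
    dab_od = np.zeros((h, w))

    # haematoxylin wash + coarse texture inside the tissue
    wash = 0.22 + 0.08 * ndi.gaussian_filter(rng.standard_normal((h, w)),
                                             sigma=max(min(h, w) / 40.0, 1.0))
    h_od[tissue] = np.clip(wash[tissue], 0.08, 0.45)
    # faint achromatic haze on the glass
    glass_od = np.abs(rng.normal(0.0, 0.004, size=(h, w)))

    boxes: List[OrientedBox] = []
    occupancy = np.zeros((h, w), dtype=bool)  # drawn somata, for separation
    attempts = 0
    while len(boxes) < spec.n_cells:
        if attempts >= _MAX_PLACEMENT_ATTEMPTS:
            raise GenerationError(
                f"placed only {len(boxes)}/{spec.n_cells} cells after "
                f"{_MAX_PLACEMENT_ATTEMPTS} attempts; lower the density or "
                f"raise tissue_fraction")
        attempts += 1
        length = rng.uniform(*spec.cell_len_range)
        aspect = rng.uniform(*spec.cell_aspect_range)
        theta = rng.uniform(-math.pi / 2.0, math.pi / 2.0)
        cx = rng.uniform(0, w)
        cy = rng.uniform(0, h)
        half_diag = math.hypot(length, length * aspect) / 2.0
        r, c = int(cy), int(cx)
        if not (0 <= r < h and 0 <= c < w):
            continue
        if dist[r, c] < half_diag + 3.0:  # box (and margin) inside tissue
            continue
        cand = canonicalize(cx, cy, length, length * aspect, theta, score=1.0)
        if any(obb_iou(cand, b) >= _PLACEMENT_MAX_IOU for b in boxes):
            continue
        window, body = _cell_patch(dab_od.shape, cand)
        r0, c0, r1, c1 = window
        # somata of distinct cells must stay separated (touching bodies
        # would fuse into one blob, which the emulation does not intend)
        grown = ndi.binary_dilation(body, iterations=3)
        if (occupancy[r0:r1, c0:c1] & grown).any():
            continue
        boxes.append(cand)
        occupancy[r0:r1, c0:c1] |= grown
        body_od = rng.uniform(*spec.dab_intensity_range)
        _draw_cell(dab_od, rng, cand, body_od, window, body)

    # distractor nuclei: haematoxylin-only, round-ish, inside tissue
    placed = 0
    attempts = 0
    while placed < spec.n_distractors and attempts < _MAX_PLACEMENT_ATTEMPTS:
        attempts += 1
        cx = rng.uniform(0, w)
        cy = rng.uniform(0, h)
        r, c = int(cy), int(cx)
        radius = rng.uniform(4.0, 7.0)
        if not (0 <= r < h and 0 <= c < w) or dist[r, c] < radius + 2:
            continue
        aspect = rng.uniform(0.7, 1.0)
        ang = rng.uniform(-math.pi / 2, math.pi / 2)
        pad = int(radius) + 3
        r0, c0 = max(r - pad, 0), max(c - pad, 0)
        r1, c1 = min(r + pad, h), min(c + pad, w)
        nuc = _ellipse_mask(r1 - r0, c1 - c0, cy - r0, cx - c0,
                            radius, radius * aspect, ang)
        od = rng.uniform(0.5, 0.9)
        sub = h_od[r0:r1, c0:c1]
        np.maximum(sub, np.where(nuc, od, 0.0), out=sub)
        placed += 1

    rgb = rgb_from_stains(h_od, dab_od)
    # achromatic haze applied uniformly so glass stays unsaturated
    rgb = np.clip(rgb.astype(float) * (1.0 - glass_od)[..., None], 0, 255)
    rgb = np.rint(rgb).astype(np.uint8)
    image = RasterImage(rgb, pixel_size_um=spec.pixel_size_um)
    return image, boxes, tissue


# --- D4 augmentation -------------------------------------------------
#
# Each transform is (name, image_fn, affine) where affine = (A, use_size)
# maps continuous coordinates (x, y) on a square of side S to
# A @ (x, y) + t(S); A is the linear part, t the S-dependent offset.

def _affine(a, b, c, d, tx, ty):
    # (x, y) -> (a x + b y + tx S, c x + d y + ty S)
    return np.array([[a, b], [c, d]], dtype=float), np.array([tx, ty], dtype=float)


AUGMENTATIONS: List[Tuple[str, Callable[[np.ndarray], np.ndarray],
                          Tuple[np.ndarray, np.ndarray]]] = [
    ("rot90", lambda a: np.rot90(a, 1), _affine(0, 1, -1, 0, 0, 1)),
    ("rot180", lambda a: np.rot90(a, 2), _affine(-1, 0, 0, -1, 1, 1)),
    ("rot270", lambda a: np.rot90(a, 3), _affine(0, -1, 1, 0, 1, 0)),
    ("fliph", lambda a: a[:, ::-1], _affine(-1, 0, 0, 1, 1, 0)),
    ("flipv", lambda a: a[::-1, :], _affine(1, 0, 0, -1, 0, 1)),
    ("transpose", lambda a: a.swapaxes(0, 1), _affine(0, 1, 1, 0, 0, 0)),
    ("antitranspose", lambda a: a[::-1, ::-1].swapaxes(0, 1),
     _affine(0, -1, -1, 0, 1, 1)),
]


def transform_box(box: OrientedBox, affine, size: float) -> OrientedBox:
    """Map a box through one D4 symmetry of an S x S image.

    The centre follows the full affine map; the orientation follows the
    linear part applied to the box's long-axis direction; the result is
    re-canonicalised (reflections reverse the sign of theta).
    """
    A, t = affine
    center = A @ np.array([box.cx, box.cy]) + t * size
    direction = A @ np.array([math.cos(box.theta), math.sin(box.theta)])
    theta = math.atan2(direction[1], direction[0])
    return canonicalize(center[0], center[1], box.w, box.h, theta,
                        box.score, box.class_id)


def augment(
    image: RasterImage, boxes: Sequence[OrientedBox]
) -> List[Tuple[str, RasterImage, List[OrientedBox]]]:
    """The 7 non-identity D4 transforms of a square image with
    consistently transformed boxes."""
    if image.width != image.height:
        raise ValidationError("augmentation requires a square image")
    size = float(image.width)
    out = []
    for name, img_fn, affine in AUGMENTATIONS:
        arr = np.ascontiguousarray(img_fn(image.pixels))
        tboxes = [transform_box(b, affine, size) for b in boxes]
        out.append((name, RasterImage(arr, image.pixel_size_um), tboxes))
    return out


def make_dataset(
    spec_template: SynthSpec,
    n_images: int,
    val_fraction: float,
    out_dir: str,
) -> dict:
    """Write a train/val dataset of synthetic slides with YOLO-OBB labels.

    The last ``ceil(val_fraction * n_images)`` base images form the
    validation split, written without augmentation; every training base
    is written together with its 7 D4-augmented copies.  An ``index.csv``
    lists every file with its seed, split and transform.  Returns split
    counts.
    """
    if not (0.0 < val_fraction < 1.0):
        raise ValidationError("val_fraction must lie in (0, 1)")
    if n_images < 1:
        raise ValidationError("n_images must be >= 1")
    n_val = math.ceil(val_fraction * n_images)
    n_train = n_images - n_val
    os.makedirs(out_dir, exist_ok=True)
    rows = []

    def _emit(split: str, stem: str, image: RasterImage,
              boxes: Sequence[OrientedBox], seed: int, transform: str) -> None:
        d = os.path.join(out_dir, split)
        os.makedirs(d, exist_ok=True)
        img_path = os.path.join(d, stem + ".tif")
        lab_path = os.path.join(d, stem + ".txt")
        write_image(image, img_path)
        write_labels(boxes, image.width, image.height, lab_path)
        rows.append({"file": os.path.join(split, stem + ".tif"),
                     "labels": os.path.join(split, stem + ".txt"),
                     "split": split, "seed": seed, "transform": transform,
                     "n_boxes": len(boxes)})

    for i in range(n_images):
        seed = spec_template.seed + i
        spec = replace(spec_template, seed=seed)
        image, boxes, _ = generate_image(spec)
        split = "val" if i >= n_train else "train"
        stem = f"img_{i:04d}"
        _emit(split, stem, image, boxes, seed, "identity")
        if split == "train":
            for name, aug_img, aug_boxes in augment(image, boxes):
                _emit(split, f"{stem}_{name}", aug_img, aug_boxes, seed, name)

    index_path = os.path.join(out_dir, "index.csv")
    with open(index_path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["file", "labels", "split", "seed", "transform", "n_boxes"])
        writer.writeheader()
        writer.writerows(rows)
    return {"n_val": n_val, "n_train_bases": n_train,
            "n_train_files": n_train * 8, "index": index_path}
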