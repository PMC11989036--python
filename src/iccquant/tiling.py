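"""Tile planning, extraction, and consolidation of per-tile detections.

Whole-slide images are processed as fixed-size square tiles.  Tiles are
laid out row-major on a stride of ``tile_size - overlap``; the last tile
on each axis is snapped back flush with the image border (no padding),
so every tile contains only real pixels and every image pixel is covered
by at least one tile.  Detections made in tile-local coordinates are
shifted into the global frame and deduplicated with a single oriented
NMS pass — an object cut by a tile seam is reported by both overlapping
tiles and survives as its best-scoring copy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import ValidationError
from .geometry import OrientedBox, nms
from .imgio import RasterImage

__all__ = [
    "TileGrid",
    "TileDetections",
    "plan_tiles",
    "extract_tiles",
    "to_global",
    "consolidate",
]


@dataclass(frozen=True)
class TileGrid:
    tile_size: int
    overlap: int
    origins: Tuple[Tuple[int, int], ...]  # (x0, y0), row-major
    image_w: int
    image_h: int

    def __len__(self) -> int:
        return len(self.origins)


@dataclass
class TileDetections:
    tile_index: int
    boxes: List[OrientedBox]


def _axis_origins(dim: int, tile: int, stride: int) -> List[int]:
    if dim <= tile:
        return [0]
    count = math.ceil((dim - tile) / stride) + 1
    origins = [min(k * stride, dim - tile) for k in range(count)]
    return origins


def plan_tiles(image_w: int, image_h: int, tile_size: int, overlap: int) -> TileGrid:
    """Plan a covering grid of ``tile_size`` x ``tile_size`` tiles.

    ``overlap`` pixels are shared between adjacent tiles; the last tile
    per axis ends exactly at the image edge.
    """
    if tile_size < 1:
        raise ValidationError("tile_size must be >= 1")
    if not (0 <= overlap < tile_size):
        raise ValidationError("need 0 <= overlap < tile_size")
    if image_w < 1 or image_h < 1:
        raise ValidationError("image must be at least 1 x 1")
    stride = tile_size - overlap
    xs = _axis_origins(image_w, tile_size, stride)
    ys = _axis_origins(image_h, tile_size, stride)
    origins = tuple((x, y) for y in ys for x in xs)
    return TileGrid(tile_size=tile_size, overlap=overlap, origins=origins,
                    image_w=image_w, image_h=image_h)


def extract_tiles(image: RasterImage, grid: TileGrid) -> List[RasterImage]:
    """Crop every planned tile out of the image.

    Tiles smaller than ``tile_size`` can only arise when the image
    itself is smaller than one tile; in that case the single tile is
    the whole image.
    """
    if (image.width, image.height) != (grid.image_w, grid.image_h):
        raise ValidationError(
            f"grid planned for {grid.image_w}x{grid.image_h} but image is "
            f"{image.width}x{image.height}")
    t = grid.tile_size
    tiles = []
    for (x0, y0) in grid.origins:
        crop = image.pixels[y0:y0 + t, x0:x0 + t]
        tiles.append(RasterImage(np.ascontiguousarray(crop),
                                 pixel_size_um=image.pixel_size_um))
    return tiles


def to_global(boxes: Sequence[OrientedBox], origin: Tuple[int, int]) -> List[OrientedBox]:
    """Shift tile-local boxes by the tile origin; shape and score unchanged."""
    x0, y0 = origin
    return [OrientedBox(b.cx + x0, b.cy + y0, b.w, b.h, b.theta, b.score, b.class_id)
            for b in boxes]


def consolidate(
    per_tile: Sequence[TileDetections],
    grid: TileGrid,
    dedup_iou: float = 0.5,
    edge_margin: Optional[int] = None,
) -> List[OrientedBox]:
    """Merge per-tile detections into one deduplicated global set.

    All boxes are mapped to the global frame and a single oriented NMS
    pass at ``dedup_iou`` removes seam duplicates.  Before NMS, boxes
    touching an *interior* tile edge (within ``edge_margin`` px; edges
    flush with the image border never count) are dropped: such boxes
    come from objects cut by the tile seam, and as long as the tile
    overlap exceeds the object extent plus twice the margin, every
    object appears whole and clear of the margin in some other tile.
    ``edge_margin`` defaults to ``min(16, overlap // 2)``; pass 0 to
    disable.  Output is sorted by score descending.
    """
    if edge_margin is None:
        edge_margin = min(16, grid.overlap // 2)
    all_boxes: List[OrientedBox] = []
    for det in per_tile:
        if not (0 <= det.tile_index < len(grid)):
            raise ValidationError(f"tile_index {det.tile_index} out of range")
        x0, y0 = grid.origins[det.tile_index]
        x1 = min(x0 + grid.tile_size, grid.image_w)
        y1 = min(y0 + grid.tile_size, grid.image_h)
        for box in to_global(det.boxes, (x0, y0)):
            if edge_margin > 0:
                cs = box.corners()
                xmin, ymin = cs.min(axis=0)
                xmax, ymax = cs.max(axis=0)
                if ((x0 > 0 and xmin < x0 + edge_margin)
                        or (y0 > 0 and ymin < y0 + edge_margin)
                        or (x1 < grid.image_w and xmax > x1 - edge_margin)
                        or (y1 < grid.image_h and ymax > y1 - edge_margin)):
                    continue
            all_boxes.append(box)
    return nms(all_boxes, dedup_iou)
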