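"""Oriented rectangles, rotated IoU and oriented non-maximum suppression.

The oriented bounding box (OBB) is the unit of both annotation and
detection throughout the package: a rectangle with centre ``(cx, cy)``,
side lengths ``(w, h)`` and rotation ``theta``, in image coordinates
(x rightward, y downward, continuous, origin at the top-left pixel
corner).  A rectangle is invariant under ``theta -> theta + pi``, so
boxes are kept in a canonical form (``w >= h``, ``theta`` in
``[-pi/2, pi/2)``) that makes equality testable.

Rotated IoU is computed analytically: the two rectangles are converted
to convex polygons, intersected by Sutherland–Hodgman clipping, and the
intersection area taken from the shoelace formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "OrientedBox",
    "canonicalize",
    "box_from_corners",
    "box_to_polygon",
    "polygon_area",
    "intersection_area",
    "obb_iou",
    "nms",
]

_HALF_PI = math.pi / 2.0


@dataclass(frozen=True)
class OrientedBox:
    """A rotated rectangle with a detection confidence.

    ``score`` is 1.0 for ground-truth annotations.  Instances are
    expected to be canonical (``w >= h``, ``theta`` in ``[-pi/2, pi/2)``);
    use :func:`canonicalize` to construct them from raw parameters.
    """

    cx: float
    cy: float
    w: float
    h: float
    theta: float
    score: float = 1.0
    class_id: int = 0

    def corners(self) -> np.ndarray:
        """Return the 4 corner points, shape (4, 2), consistent winding."""
        c, s = math.cos(self.theta), math.sin(self.theta)
        hw, hh = self.w / 2.0, self.h / 2.0
        local = np.array(
            [[-hw, -hh], [hw, -hh], [hw, hh], [-hw, hh]], dtype=float
        )
        rot = np.array([[c, -s], [s, c]])
        return local @ rot.T + np.array([self.cx, self.cy])

    def area(self) -> float:
        return self.w * self.h


def canonicalize(
    cx: float,
    cy: float,
    w: float,
    h: float,
    theta: float,
    score: float = 1.0,
    class_id: int = 0,
) -> OrientedBox:
    """Build a canonical :class:`OrientedBox` from raw parameters.

    If ``w < h`` the sides are swapped and ``theta`` advanced by pi/2;
    ``theta`` is then wrapped into ``[-pi/2, pi/2)``.  The geometric
    footprint is unchanged.
    """
    if not (w > 0 and h > 0):
        raise ValidationError(f"box sides must be positive, got w={w}, h={h}")
    if not math.isfinite(theta):
        raise ValidationError("theta must be finite")
    if not (0.0 <= score <= 1.0):
        raise ValidationError(f"score must lie in [0, 1], got {score}")
    if w < h:
        w, h = h, w
        theta = theta + _HALF_PI
    # wrap into [-pi/2, pi/2); the rectangle has period pi in theta
    theta = math.remainder(theta, math.pi)
    if theta >= _HALF_PI:  # remainder returns (-pi/2, pi/2] boundary case
        theta -= math.pi
    return OrientedBox(float(cx), float(cy), float(w), float(h), float(theta),
                       float(score), int(class_id))


def box_from_corners(
    corners: Sequence[Sequence[float]],
    score: float = 1.0,
    class_id: int = 0,
) -> OrientedBox:
    """Recover a canonical box from 4 corner points in consecutive order.

    The corners may use either winding; the rectangle is reconstructed
    from the first edge and the corner diagonal, which is exact for true
    rectangles and a least-surprise fit for slightly perturbed ones.
    """
    pts = np.asarray(corners, dtype=float)
    if pts.shape != (4, 2):
        raise ValidationError(f"expected 4 corner points, got shape {pts.shape}")
    center = pts.mean(axis=0)
    e1 = pts[1] - pts[0]
    e2 = pts[3] - pts[0]
    w = float(np.hypot(*e1))
    h = float(np.hypot(*e2))
    theta = math.atan2(e1[1], e1[0])
    return canonicalize(center[0], center[1], w, h, theta, score, class_id)


def box_to_polygon(box: OrientedBox) -> np.ndarray:
    """Corner polygon of a box with positive (counter-clockwise in the
    y-down frame) signed area."""
    pts = box.corners()
    if _signed_area(pts) < 0:
        pts = pts[::-1]
    return pts


def _signed_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def polygon_area(pts: np.ndarray) -> float:
    """Absolute polygon area via the shoelace formula."""
    return abs(_signed_area(np.asarray(pts, dtype=float)))


def _clip_against_edge(subject: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Clip ``subject`` by the half-plane left of directed edge a->b
    (inside for positively wound clip polygons)."""
    if len(subject) == 0:
        return subject
    edge = b - a
    # cross(edge, p - a) >= 0  <=>  p inside
    d = (subject[:, 0] - a[0]) * edge[1] - (subject[:, 1] - a[1]) * edge[0]
    inside = -d >= 0.0  # cross(edge, p-a) = edge.x*dy - edge.y*dx = -d
    out: List[np.ndarray] = []
    n = len(subject)
    for i in range(n):
        j = (i + 1) % n
        p, q = subject[i], subject[j]
        pin, qin = inside[i], inside[j]
        if pin:
            out.append(p)
        if pin != qin:
            # intersection of segment pq with the edge line
            dp, dq = -d[i], -d[j]
            t = dp / (dp - dq)
            out.append(p + t * (q - p))
    return np.array(out) if out else np.empty((0, 2))


def intersection_area(p: np.ndarray, q: np.ndarray) -> float:
    """Area of the intersection of two convex polygons (Sutherland–Hodgman).

    Both polygons must be convex; winding is normalised internally.
    Degenerate clip results (fewer than 3 vertices) have zero area.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if _signed_area(p) < 0:
        p = p[::-1]
    if _signed_area(q) < 0:
        q = q[::-1]
    clipped = p
    n = len(q)
    for i in range(n):
        clipped = _clip_against_edge(clipped, q[i], q[(i + 1) % n])
        if len(clipped) < 3:
            return 0.0
    return polygon_area(clipped)


def obb_iou(a: OrientedBox, b: OrientedBox) -> float:
    """Rotated intersection-over-union of two oriented boxes, in [0, 1].

    Defined as 0 for a degenerate zero-area union.
    """
    inter = intersection_area(box_to_polygon(a), box_to_polygon(b))
    union = a.area() + b.area() - inter
    if union <= 0.0:
        return 0.0
    return min(max(inter / union, 0.0), 1.0)


def nms(boxes: Sequence[OrientedBox], iou_thresh: float = 0.5) -> List[OrientedBox]:
    """Greedy oriented non-maximum suppression.

    Boxes are visited in descending score (ties broken by input index,
    for determinism); a box is kept iff its IoU with every already-kept
    box is below ``iou_thresh``.  The default threshold 0.5 matches the
    IoU convention of mAP50.
    """
    if not (0.0 < iou_thresh <= 1.0):
        raise ValidationError(f"iou_thresh must lie in (0, 1], got {iou_thresh}")
    order = sorted(range(len(boxes)), key=lambda i: (-boxes[i].score, i))
    kept: List[OrientedBox] = []
    for i in order:
        cand = boxes[i]
        if all(obb_iou(cand, k) < iou_thresh for k in kept):
            kept.append(cand)
    return kept
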