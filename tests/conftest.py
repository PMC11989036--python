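import math

import numpy as np
import pytest
from hypothesis import settings

from iccquant.geometry import OrientedBox, canonicalize

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


def random_boxes(rng: np.random.Generator, n: int,
                 field: float = 200.0,
                 side_range=(5.0, 50.0),
                 with_scores: bool = True):
    """Random canonical boxes on a square field, for property tests."""
    boxes = []
    for _ in range(n):
        w = rng.uniform(*side_range)
        h = rng.uniform(*side_range)
        boxes.append(canonicalize(
            cx=rng.uniform(0.3 * field, 0.7 * field),
            cy=rng.uniform(0.3 * field, 0.7 * field),
            w=w, h=h,
            theta=rng.uniform(-math.pi / 2, math.pi / 2),
            score=float(rng.uniform(0.05, 1.0)) if with_scores else 1.0,
        ))
    return boxes


def rasterized_iou(a: OrientedBox, b: OrientedBox, step: float = 0.1) -> float:
    """Independent IoU oracle: point-in-rectangle sampling on a fine grid
    restricted to the joint bounding box."""
    cs = np.vstack([a.corners(), b.corners()])
    x0, y0 = cs.min(axis=0) - step
    x1, y1 = cs.max(axis=0) + step
    xs = np.arange(x0, x1, step) + step / 2
    ys = np.arange(y0, y1, step) + step / 2
    xx, yy = np.meshgrid(xs, ys)

    def inside(box):
        dx = xx - box.cx
        dy = yy - box.cy
        c, s = math.cos(box.theta), math.sin(box.theta)
        u = dx * c + dy * s
        v = -dx * s + dy * c
        return (np.abs(u) <= box.w / 2) & (np.abs(v) <= box.h / 2)

    ma, mb = inside(a), inside(b)
    inter = np.count_nonzero(ma & mb)
    union = np.count_nonzero(ma | mb)
    return inter / union if union else 0.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
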