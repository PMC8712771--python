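"""Shared test oracles: pixel-rasterization geometry and brute-force AP.

These deliberately avoid the analytic code paths they are used to check.
"""

from __future__ import annotations

import numpy as np
import pytest

from rssr.geometry import Box


def rasterize(box: Box, width: int, height: int) -> np.ndarray:
    """Boolean pixel mask of an integer-coordinate box on a W x H grid."""
    mask = np.zeros((height, width), dtype=bool)
    x0, y0 = max(0, int(box.x_min)), max(0, int(box.y_min))
    x1, y1 = min(width, int(box.x_max)), min(height, int(box.y_max))
    if x1 > x0 and y1 > y0:
        mask[y0:y1, x0:x1] = True
    return mask


def raster_iou(a: Box, b: Box, width: int = 128, height: int = 128) -> float:
    """IOU by counting pixels of the two rasterized boxes."""
    ma, mb = rasterize(a, width, height), rasterize(b, width, height)
    union = np.count_nonzero(ma | mb)
    return np.count_nonzero(ma & mb) / union


def brute_force_ap(flags: list[bool], n_gt: int) -> float:
    """AP summed TP by TP: the i-th true positive at rank k contributes
    (i/k) * (1/n_gt) — an independent route to the staircase sum."""
    ap = 0.0
    n_tp = 0
    for k, flag in enumerate(flags, start=1):
        if flag:
            n_tp += 1
            ap += (n_tp / k) / n_gt
    return ap


def random_box(rng: np.random.Generator, max_coord: int = 100, max_side: int = 40) -> Box:
    x0 = int(rng.integers(0, max_coord - 1))
    y0 = int(rng.integers(0, max_coord - 1))
    w = int(rng.integers(1, max_side + 1))
    h = int(rng.integers(1, max_side + 1))
    return Box(x0, y0, min(x0 + w, max_coord), min(y0 + h, max_coord))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
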