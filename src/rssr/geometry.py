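"""Axis-aligned box arithmetic and intersection-over-union.

Coordinates are continuous, origin at the top-left of the image, with the
half-open convention ``[x_min, x_max) x [y_min, y_max)``.  Half-open
intervals make a grid of tiles a true partition of the pixel plane: no
pixel is counted twice and none is dropped, which is what the half-grain
bookkeeping downstream relies on.

IOU is computed analytically on rectangles.  A pixel-rasterization
equivalent exists only as a test oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum


class GeometryError(ValueError):
    """Invalid (degenerate or malformed) box input."""


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle ``[x_min, x_max) x [y_min, y_max)`` with positive area."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise GeometryError(
                f"box must have positive area, got "
                f"({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def translate(self, dx: float, dy: float) -> "Box":
        return Box(self.x_min + dx, self.y_min + dy, self.x_max + dx, self.y_max + dy)

    def contains(self, other: "Box") -> bool:
        return (
            self.x_min <= other.x_min
            and self.y_min <= other.y_min
            and other.x_max <= self.x_max
            and other.y_max <= self.y_max
        )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)


def intersection_area(a: Box, b: Box) -> float:
    """Area of the rectangle intersection; 0 when disjoint."""
    w = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    h = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if w <= 0.0 or h <= 0.0:
        return 0.0
    return w * h


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes.

    Symmetric, in ``[0, 1]``; 1 exactly when the boxes coincide and 0 when
    they are disjoint.  This is the pixel-set Jaccard index of the two
    rectangles, evaluated in closed form.
    """
    inter = intersection_area(a, b)
    union = a.area + b.area - inter
    return inter / union


def clip(a: Box, frame: Box) -> Box | None:
    """Intersection rectangle of ``a`` with ``frame``, or None when disjoint.

    ``area(clip(a, frame)) <= area(a)`` always holds, with equality iff the
    frame contains ``a``.
    """
    x_min = max(a.x_min, frame.x_min)
    y_min = max(a.y_min, frame.y_min)
    x_max = min(a.x_max, frame.x_max)
    y_max = min(a.y_max, frame.y_max)
    if x_min >= x_max or y_min >= y_max:
        return None
    return Box(x_min, y_min, x_max, y_max)


class GrainLabel(str, Enum):
    """Grain category as annotated/detected.

    ``full``  -- filled grain (raised, center-bright appearance).
    ``empty`` -- unfilled grain (flat, often showing a central crack).
    ``half``  -- a grain truncated by a tile boundary during cropping.
    """

    FULL = "full"
    EMPTY = "empty"
    HALF = "half"


class HalfSubtype(str, Enum):
    """Provenance of a half grain: what it was before the cut.

    ``H-full``/``H-empty`` record the originating category of a half grain
    when it is known (ground truth after tiling); detections of real
    detectors typically report plain ``half`` (``unknown``).
    """

    H_FULL = "H-full"
    H_EMPTY = "H-empty"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class GrainCategory:
    """Label plus optional half-grain provenance subtype."""

    label: GrainLabel
    half_subtype: HalfSubtype = HalfSubtype.UNKNOWN

    def __post_init__(self) -> None:
        if self.half_subtype is not HalfSubtype.UNKNOWN and self.label is not GrainLabel.HALF:
            raise GeometryError(
                f"half_subtype {self.half_subtype.value!r} is only meaningful "
                f"for label 'half', got {self.label.value!r}"
            )


# convenience singletons for the three plain categories
FULL = GrainCategory(GrainLabel.FULL)
EMPTY = GrainCategory(GrainLabel.EMPTY)
HALF = GrainCategory(GrainLabel.HALF)
H_FULL = GrainCategory(GrainLabel.HALF, HalfSubtype.H_FULL)
H_EMPTY = GrainCategory(GrainLabel.HALF, HalfSubtype.H_EMPTY)


@dataclass(frozen=True)
class GrainBox:
    """One annotated or detected grain: box + category + confidence.

    Ground-truth grains carry confidence 1.0; detector outputs carry the
    detector's score in ``[0, 1]``.
    """

    box: Box
    category: GrainCategory
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0) or math.isnan(self.confidence):
            raise GeometryError(f"confidence must be in [0, 1], got {self.confidence}")

    @property
    def label(self) -> GrainLabel:
        return self.category.label

    def translate(self, dx: float, dy: float) -> "GrainBox":
        return GrainBox(self.box.translate(dx, dy), self.category, self.confidence)
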