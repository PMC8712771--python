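"""Pascal VOC XML annotation I/O (LabelImg dialect).

Coordinate convention: the XML files store integer corners that are
1-based and inclusive, the common LabelImg dialect, so a box written as
``(xmin, ymin, xmax, ymax)`` covers pixels ``xmin..xmax`` counting from 1.
Internally all boxes are 0-based, half-open and continuous; the mapping is

    internal x_min = file xmin - 1        file xmin = round(x_min) + 1
    internal x_max = file xmax            file xmax = round(x_max)

so a full-width box on a W-pixel image is ``[0, W)`` internally and
``(1, W)`` in the file.  Writing integerizes fractional corners by
rounding; reading a written file is the identity on integer-corner
annotations.

The category vocabulary is closed: ``full``, ``empty``, ``half``,
``H-full``, ``H-empty`` (case-insensitive); anything else is rejected.
"""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import IO, Union

from .geometry import (
    Box,
    GeometryError,
    GrainBox,
    GrainCategory,
    GrainLabel,
    HalfSubtype,
)

PathLike = Union[str, os.PathLike]


class VocError(ValueError):
    """Malformed or out-of-contract VOC annotation content."""


_CATEGORY_NAMES: dict[str, GrainCategory] = {
    "full": GrainCategory(GrainLabel.FULL),
    "empty": GrainCategory(GrainLabel.EMPTY),
    "half": GrainCategory(GrainLabel.HALF),
    "h-full": GrainCategory(GrainLabel.HALF, HalfSubtype.H_FULL),
    "h-empty": GrainCategory(GrainLabel.HALF, HalfSubtype.H_EMPTY),
}


def category_name(category: GrainCategory) -> str:
    """Canonical object name for a category (``H-full``/``H-empty`` when known)."""
    if category.half_subtype is not HalfSubtype.UNKNOWN:
        return category.half_subtype.value
    return category.label.value


def parse_category(name: str) -> GrainCategory:
    key = name.strip().lower()
    if key not in _CATEGORY_NAMES:
        raise VocError(
            f"unknown grain category {name!r}; expected one of "
            f"full, empty, half, H-full, H-empty"
        )
    return _CATEGORY_NAMES[key]


@dataclass(frozen=True)
class AnnotatedImage:
    """An image id, its pixel dimensions, and its grain annotations."""

    image_id: str
    width: int
    height: int
    grains: tuple[GrainBox, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise VocError(f"image dimensions must be positive, got {self.width}x{self.height}")
        object.__setattr__(self, "grains", tuple(self.grains))
        frame = Box(0, 0, self.width, self.height)
        for g in self.grains:
            if not frame.contains(g.box):
                raise VocError(
                    f"grain box {g.box.as_tuple()} outside image bounds "
                    f"{self.width}x{self.height} in {self.image_id!r}"
                )

    def counts(self) -> dict[str, int]:
        """Tally of plain labels (full/empty/half)."""
        out = {"full": 0, "empty": 0, "half": 0}
        for g in self.grains:
            out[g.label.value] += 1
        return out


def read_voc(source: Union[PathLike, IO[bytes], IO[str]]) -> AnnotatedImage:
    """Parse a LabelImg-style VOC XML file into an :class:`AnnotatedImage`.

    ``H-full``/``H-empty`` object names yield label ``half`` with the
    matching provenance subtype.  Confidence is 1.0 (annotations are ground
    truth).  Unknown category names, boxes outside the image and malformed
    XML all raise :class:`VocError`.
    """
    try:
        tree = ET.parse(source)
    except ET.ParseError as exc:
        raise VocError(f"malformed VOC XML: {exc}") from exc
    root = tree.getroot()

    size = root.find("size")
    if size is None or size.find("width") is None or size.find("height") is None:
        raise VocError("VOC XML missing <size><width>/<height>")
    width = int(size.findtext("width"))
    height = int(size.findtext("height"))
    image_id = root.findtext("filename") or ""
    image_id = os.path.splitext(os.path.basename(image_id))[0]

    grains: list[GrainBox] = []
    for obj in root.findall("object"):
        name = obj.findtext("name")
        if name is None:
            raise VocError("<object> missing <name>")
        category = parse_category(name)
        bnd = obj.find("bndbox")
        if bnd is None:
            raise VocError(f"<object> {name!r} missing <bndbox>")
        try:
            xmin = float(bnd.findtext("xmin"))
            ymin = float(bnd.findtext("ymin"))
            xmax = float(bnd.findtext("xmax"))
            ymax = float(bnd.findtext("ymax"))
        except (TypeError, ValueError) as exc:
            raise VocError(f"non-numeric <bndbox> in object {name!r}") from exc
        # 1-based inclusive file corners -> 0-based half-open
        try:
            box = Box(xmin - 1.0, ymin - 1.0, xmax, ymax)
        except GeometryError as exc:
            raise VocError(f"degenerate box in object {name!r}: {exc}") from exc
        grains.append(GrainBox(box, category, confidence=1.0))

    try:
        return AnnotatedImage(image_id, width, height, tuple(grains))
    except VocError:
        raise


def write_voc(annotated: AnnotatedImage, destination: Union[PathLike, IO[bytes]]) -> None:
    """Write an :class:`AnnotatedImage` as LabelImg-style VOC XML.

    An empty grain list produces a legal annotation with zero ``<object>``
    nodes (a background image).  Fractional box corners are rounded to the
    integer pixel grid; :func:`read_voc` of the result reproduces the
    integerized annotation exactly.
    """
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = "images"
    ET.SubElement(root, "filename").text = f"{annotated.image_id}.png"
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(annotated.width)
    ET.SubElement(size, "height").text = str(annotated.height)
    ET.SubElement(size, "depth").text = "3"
    ET.SubElement(root, "segmented").text = "0"

    for g in annotated.grains:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = category_name(g.category)
        ET.SubElement(obj, "pose").text = "Unspecified"
        ET.SubElement(obj, "truncated").text = "0"
        ET.SubElement(obj, "difficult").text = "0"
        bnd = ET.SubElement(obj, "bndbox")
        # 0-based half-open -> 1-based inclusive integer corners
        ET.SubElement(bnd, "xmin").text = str(int(round(g.box.x_min)) + 1)
        ET.SubElement(bnd, "ymin").text = str(int(round(g.box.y_min)) + 1)
        ET.SubElement(bnd, "xmax").text = str(int(round(g.box.x_max)))
        ET.SubElement(bnd, "ymax").text = str(int(round(g.box.y_max)))

    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(destination, encoding="unicode" if hasattr(destination, "write") and not _is_binary(destination) else "utf-8")


def _is_binary(destination) -> bool:
    mode = getattr(destination, "mode", "b")
    return "b" in mode
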