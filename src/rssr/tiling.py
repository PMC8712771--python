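"""Grid tiling of panicle images with half-grain relabeling.

A full-resolution image is partitioned into a ``tiles_x x tiles_y`` grid of
non-overlapping tiles (stride = tile size).  Grains that straddle a tile
boundary are re-labeled ``half`` in every tile that keeps a large-enough
part, with a provenance subtype recording the original category
(full -> H-full, empty -> H-empty).  A grain cut by exactly one interior
boundary therefore contributes exactly two half boxes — the premise of the
``NH/2`` term in the corrected seed-setting-rate estimator.

When the grid does not divide the image evenly, the last row/column of
tiles absorbs the remainder, so the tiles always partition the pixel grid
exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    Box,
    GrainBox,
    GrainCategory,
    GrainLabel,
    HalfSubtype,
    clip,
)
from .voc import AnnotatedImage

#: Default fraction of a grain's area a clipped part must keep to be
#: emitted as a half grain; smaller slivers are unlabelable and dropped.
DEFAULT_MIN_AREA_FRACTION = 0.15

_HALF_SUBTYPE_OF = {
    GrainLabel.FULL: HalfSubtype.H_FULL,
    GrainLabel.EMPTY: HalfSubtype.H_EMPTY,
}


class TilingError(ValueError):
    pass


@dataclass(frozen=True)
class TileGrid:
    """A deterministic left-to-right, top-to-bottom tiling of an image."""

    image_w: int
    image_h: int
    tiles_x: int
    tiles_y: int

    def __post_init__(self) -> None:
        if self.image_w <= 0 or self.image_h <= 0:
            raise TilingError("image dimensions must be positive")
        if self.tiles_x < 1 or self.tiles_y < 1:
            raise TilingError("tile counts must be >= 1")
        if self.tiles_x > self.image_w or self.tiles_y > self.image_h:
            raise TilingError(
                f"grid {self.tiles_x}x{self.tiles_y} exceeds image "
                f"{self.image_w}x{self.image_h}"
            )

    @property
    def tile_w(self) -> int:
        """Base tile width (last column absorbs any remainder)."""
        return self.image_w // self.tiles_x

    @property
    def tile_h(self) -> int:
        return self.image_h // self.tiles_y

    @property
    def n_tiles(self) -> int:
        return self.tiles_x * self.tiles_y

    def frame(self, col: int, row: int) -> Box:
        """Pixel rectangle of tile ``(col, row)`` in image coordinates."""
        if not (0 <= col < self.tiles_x and 0 <= row < self.tiles_y):
            raise TilingError(f"tile index ({col}, {row}) outside grid")
        x0 = col * self.tile_w
        y0 = row * self.tile_h
        x1 = self.image_w if col == self.tiles_x - 1 else x0 + self.tile_w
        y1 = self.image_h if row == self.tiles_y - 1 else y0 + self.tile_h
        return Box(x0, y0, x1, y1)

    def frames(self) -> list[tuple[tuple[int, int], Box]]:
        """All ((col, row), frame) pairs in row-major (reading) order."""
        return [
            ((c, r), self.frame(c, r))
            for r in range(self.tiles_y)
            for c in range(self.tiles_x)
        ]


def plan_grid(image_w: int, image_h: int, tiles_x: int, tiles_y: int) -> TileGrid:
    """Plan a ``tiles_x x tiles_y`` grid over an ``image_w x image_h`` image."""
    return TileGrid(image_w=image_w, image_h=image_h, tiles_x=tiles_x, tiles_y=tiles_y)


@dataclass(frozen=True)
class Tile:
    """One tile: grid index, frame in image coordinates, tile-local grains."""

    grid_index: tuple[int, int]
    frame: Box
    grains: tuple[GrainBox, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "grains", tuple(self.grains))
        local = Box(0, 0, self.frame.width, self.frame.height)
        for g in self.grains:
            if not local.contains(g.box):
                raise TilingError(
                    f"grain box {g.box.as_tuple()} outside tile frame "
                    f"{self.frame.width}x{self.frame.height}"
                )

    @property
    def is_background(self) -> bool:
        """True iff the tile carries no grain annotations."""
        return len(self.grains) == 0

    def name(self, image_id: str) -> str:
        col, row = self.grid_index
        return f"{image_id}_r{row}_c{col}"


def cut_annotations(
    annotated: AnnotatedImage,
    grid: TileGrid,
    min_area_fraction: float = DEFAULT_MIN_AREA_FRACTION,
) -> list[Tile]:
    """Distribute grains over the tiles of ``grid``, relabeling cut grains.

    For each grain and tile let ``f`` be the fraction of the grain's area
    inside the tile:

    * ``f == 1``  — the grain is copied unchanged (category preserved);
    * ``min_area_fraction <= f < 1`` — a ``half`` grain is emitted with
      subtype inherited from the original category and box clipped to the
      tile, in tile-local coordinates;
    * ``0 < f < min_area_fraction`` — the sliver is dropped.

    A grain cut by a grid corner can yield 3–4 half boxes; this biases the
    downstream ``NH/2`` correction, so a warning is issued when it happens.
    """
    if not (0.0 <= min_area_fraction < 1.0):
        raise TilingError(f"min_area_fraction must be in [0, 1), got {min_area_fraction}")
    if grid.image_w != annotated.width or grid.image_h != annotated.height:
        raise TilingError(
            f"grid planned for {grid.image_w}x{grid.image_h} does not match "
            f"image {annotated.width}x{annotated.height}"
        )

    per_tile: dict[tuple[int, int], list[GrainBox]] = {
        idx: [] for idx, _ in grid.frames()
    }
    for grain in annotated.grains:
        parts = 0
        for idx, frame in grid.frames():
            clipped = clip(grain.box, frame)
            if clipped is None:
                continue
            f = clipped.area / grain.box.area
            local = clipped.translate(-frame.x_min, -frame.y_min)
            if f >= 1.0 - 1e-12:
                per_tile[idx].append(GrainBox(local, grain.category, grain.confidence))
                parts += 1
            elif f >= min_area_fraction:
                subtype = _HALF_SUBTYPE_OF.get(grain.label, grain.category.half_subtype)
                category = GrainCategory(GrainLabel.HALF, subtype)
                per_tile[idx].append(GrainBox(local, category, grain.confidence))
                parts += 1
        if parts > 2:
            warnings.warn(
                f"grain {grain.box.as_tuple()} cut into {parts} parts "
                f"(corner cut); NH/2 will overcount it",
                stacklevel=2,
            )

    return [
        Tile(grid_index=idx, frame=frame, grains=tuple(per_tile[idx]))
        for idx, frame in grid.frames()
    ]


def to_image_coords(tile: Tile, grain: GrainBox) -> GrainBox:
    """Map a tile-local grain box back to image coordinates."""
    local = Box(0, 0, tile.frame.width, tile.frame.height)
    if not local.contains(grain.box):
        raise TilingError(
            f"grain box {grain.box.as_tuple()} outside tile of size "
            f"{tile.frame.width}x{tile.frame.height}"
        )
    return grain.translate(tile.frame.x_min, tile.frame.y_min)


def crop_image(image: np.ndarray, grid: TileGrid) -> list[np.ndarray]:
    """Cut an image array (H x W [x C]) into pixel-exact tiles in grid order.

    Stacking the tiles back in grid order reproduces the original image
    bit-for-bit.
    """
    if image.shape[0] != grid.image_h or image.shape[1] != grid.image_w:
        raise TilingError(
            f"image shape {image.shape[:2]} does not match grid "
            f"{grid.image_h}x{grid.image_w} (rows x cols)"
        )
    tiles = []
    for _, frame in grid.frames():
        tiles.append(
            image[int(frame.y_min) : int(frame.y_max), int(frame.x_min) : int(frame.x_max)].copy()
        )
    return tiles
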