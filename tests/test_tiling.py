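"""Grid planning, annotation cutting with half relabeling, coordinate maps."""

import numpy as np
import pytest

from rssr.geometry import Box, GrainBox, GrainCategory, GrainLabel, HalfSubtype, clip
from rssr.tiling import (
    Tile,
    TileGrid,
    TilingError,
    crop_image,
    cut_annotations,
    plan_grid,
    to_image_coords,
)
from rssr.voc import AnnotatedImage


def grain(x0, y0, x1, y1, label=GrainLabel.FULL):
    return GrainBox(Box(x0, y0, x1, y1), GrainCategory(label))


class TestPlanGrid:
    def test_capture_scale_grid(self):
        """A 6x4 grid over a 4032x3024 image gives 24 tiles of 672x756."""
        grid = plan_grid(4032, 3024, 6, 4)
        assert grid.n_tiles == 24
        assert (grid.tile_w, grid.tile_h) == (672, 756)
        for _, frame in grid.frames():
            assert (frame.width, frame.height) == (672, 756)

    def test_identity_grid(self):
        grid = plan_grid(100, 100, 1, 1)
        assert grid.frames() == [((0, 0), Box(0, 0, 100, 100))]

    def test_remainder_absorbed_by_last_row_and_column(self):
        grid = plan_grid(10, 10, 3, 3)
        widths = [grid.frame(c, 0).width for c in range(3)]
        heights = [grid.frame(0, r).height for r in range(3)]
        assert widths == [3, 3, 4] and heights == [3, 3, 4]
        assert sum(widths) == 10 and sum(heights) == 10

    def test_partition_covers_every_pixel_exactly_once(self):
        grid = plan_grid(37, 23, 5, 3)
        cover = np.zeros((23, 37), dtype=int)
        for _, f in grid.frames():
            cover[int(f.y_min) : int(f.y_max), int(f.x_min) : int(f.x_max)] += 1
        assert (cover == 1).all()

    def test_oversized_grid_rejected(self):
        with pytest.raises(TilingError):
            plan_grid(10, 10, 11, 1)


class TestCutAnnotations:
    GRID = plan_grid(200, 100, 2, 1)  # boundary at x = 100

    def test_uncut_grain_copied_unchanged(self):
        ann = AnnotatedImage("a", 200, 100, (grain(10, 10, 40, 25),))
        tiles = cut_annotations(ann, self.GRID)
        assert len(tiles[0].grains) == 1 and tiles[1].is_background
        g = tiles[0].grains[0]
        assert g.label is GrainLabel.FULL
        assert g.box == Box(10, 10, 40, 25)

    @pytest.mark.parametrize(
        "label, subtype",
        [(GrainLabel.FULL, HalfSubtype.H_FULL), (GrainLabel.EMPTY, HalfSubtype.H_EMPTY)],
    )
    def test_straddling_grain_becomes_two_halves_with_provenance(self, label, subtype):
        # 60% in the left tile, 40% in the right
        ann = AnnotatedImage("a", 200, 100, (grain(70, 10, 120, 30, label),))
        tiles = cut_annotations(ann, self.GRID, min_area_fraction=0.15)
        left, right = tiles[0].grains, tiles[1].grains
        assert len(left) == 1 and len(right) == 1
        for g in (*left, *right):
            assert g.label is GrainLabel.HALF
            assert g.category.half_subtype is subtype
        assert left[0].box == Box(70, 10, 100, 30)
        assert right[0].box == Box(0, 10, 20, 30)  # tile-local coordinates

    def test_sliver_below_threshold_dropped(self):
        # 95% left, 5% sliver right: one half box total
        ann = AnnotatedImage("a", 200, 100, (grain(62, 10, 102, 30),))
        tiles = cut_annotations(ann, self.GRID, min_area_fraction=0.15)
        assert len(tiles[0].grains) == 1
        assert tiles[0].grains[0].label is GrainLabel.HALF
        assert tiles[1].is_background

    def test_corner_cut_warns_about_extra_parts(self):
        grid = plan_grid(200, 200, 2, 2)
        ann = AnnotatedImage("a", 200, 200, (grain(90, 90, 110, 110),))
        with pytest.warns(UserWarning, match="4 parts"):
            tiles = cut_annotations(ann, grid, min_area_fraction=0.0)
        assert sum(len(t.grains) for t in tiles) == 4

    def test_count_conservation_for_interior_grains(self, rng):
        """Grains that never cross boundaries keep their per-category counts."""
        grid = plan_grid(300, 200, 3, 2)
        grains = []
        for _ in range(60):
            col = int(rng.integers(0, 3))
            row = int(rng.integers(0, 2))
            f = grid.frame(col, row)
            x0 = float(rng.uniform(f.x_min + 1, f.x_max - 12))
            y0 = float(rng.uniform(f.y_min + 1, f.y_max - 12))
            label = GrainLabel.FULL if rng.random() < 0.7 else GrainLabel.EMPTY
            grains.append(grain(x0, y0, x0 + 10, y0 + 10, label))
        ann = AnnotatedImage("a", 300, 200, tuple(grains))
        tiles = cut_annotations(ann, grid)
        tallies = {"full": 0, "empty": 0, "half": 0}
        for t in tiles:
            for g in t.grains:
                tallies[g.label.value] += 1
        assert tallies["half"] == 0
        assert tallies["full"] == sum(1 for g in grains if g.label is GrainLabel.FULL)
        assert tallies["empty"] == sum(1 for g in grains if g.label is GrainLabel.EMPTY)

    def test_half_pairing_for_single_boundary_cuts(self, rng):
        """A grain crossing exactly one interior boundary yields exactly 2 halves."""
        grid = plan_grid(300, 200, 3, 2)
        # boxes straddling vertical boundary x=100, split 50/50, away from y=100
        grains = tuple(
            grain(90 + i, 10 + 15 * i, 110 + i, 20 + 15 * i) for i in range(5)
        )
        ann = AnnotatedImage("a", 300, 200, grains)
        tiles = cut_annotations(ann, grid, min_area_fraction=0.15)
        halves = [g for t in tiles for g in t.grains if g.label is GrainLabel.HALF]
        assert len(halves) == 2 * len(grains)

    def test_grid_image_mismatch_rejected(self):
        ann = AnnotatedImage("a", 100, 100, ())
        with pytest.raises(TilingError, match="does not match"):
            cut_annotations(ann, self.GRID)

    def test_determinism(self):
        ann = AnnotatedImage("a", 200, 100, (grain(70, 10, 120, 30),))
        assert cut_annotations(ann, self.GRID) == cut_annotations(ann, self.GRID)


class TestCoordinateMaps:
    def test_translation_to_image_frame(self):
        tile = Tile(grid_index=(1, 0), frame=Box(672, 0, 1344, 756))
        g = grain(10, 10, 20, 20)
        mapped = to_image_coords(tile, g)
        assert mapped.box == Box(682, 10, 692, 20)

    def test_out_of_tile_box_rejected(self):
        tile = Tile(grid_index=(0, 0), frame=Box(0, 0, 50, 50))
        with pytest.raises(TilingError):
            to_image_coords(tile, grain(40, 40, 60, 60))

    def test_round_trip_recovers_uncut_grains(self, rng):
        """Tiling then mapping back to image coordinates is the identity."""
        grid = plan_grid(4032, 3024, 6, 4)
        grains = []
        for _ in range(100):
            x0 = float(rng.integers(0, 4032 - 30))
            y0 = float(rng.integers(0, 3024 - 30))
            grains.append(grain(x0, y0, x0 + 25, y0 + 25))
        ann = AnnotatedImage("a", 4032, 3024, tuple(grains))
        tiles = cut_annotations(ann, grid, min_area_fraction=0.0)
        recovered = sorted(
            (to_image_coords(t, g).box.as_tuple()
             for t in tiles for g in t.grains if g.label is not GrainLabel.HALF),
        )
        uncut = []
        for g in grains:
            parts = sum(1 for _, f in grid.frames() if clip(g.box, f) is not None)
            if parts == 1:
                uncut.append(g.box.as_tuple())
        assert recovered == sorted(uncut)


class TestCropImage:
    def test_identity_grid_returns_original(self, rng):
        image = rng.integers(0, 255, size=(50, 80, 3), dtype=np.uint8)
        tiles = crop_image(image, plan_grid(80, 50, 1, 1))
        assert len(tiles) == 1 and np.array_equal(tiles[0], image)

    def test_reassembly_is_bit_exact(self, rng):
        image = rng.integers(0, 255, size=(23, 37), dtype=np.uint8)
        grid = plan_grid(37, 23, 5, 3)
        tiles = crop_image(image, grid)
        rebuilt = np.zeros_like(image)
        for (_, f), t in zip(grid.frames(), tiles):
            rebuilt[int(f.y_min) : int(f.y_max), int(f.x_min) : int(f.x_max)] = t
        assert np.array_equal(rebuilt, image)

    def test_tile_origin_matches_image_pixel(self, rng):
        image = rng.integers(0, 255, size=(40, 60), dtype=np.uint8)
        grid = plan_grid(60, 40, 3, 2)
        tiles = crop_image(image, grid)
        for (idx, f), t in zip(grid.frames(), tiles):
            assert t[0, 0] == image[int(f.y_min), int(f.x_min)]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(TilingError):
            crop_image(np.zeros((10, 10)), plan_grid(20, 20, 2, 2))
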