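"""Trained-model-free baseline grain detector and the end-to-end pipeline.

Real CNN detectors are out of scope here; they plug in through the
:class:`Detector` protocol (any object with ``detect(tile_image) ->
list[GrainBox]``).  The :class:`ThresholdDetector` is a classical
stand-in that works on the synthetic darkroom scenes: global automatic
thresholding against the dark background, connected components within
area bounds, and a shading-based full/empty classifier — full grains are
center-bright (raised), empty grains are darker at the medial crack than
over the rest of the grain body.  Components touching the tile border
(within a 1 px margin) are classified ``half``, mirroring how half grains
arise from tiling.

The detector is deterministic: identical tiles give identical detections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Protocol, Sequence, runtime_checkable

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .geometry import (
    Box,
    EMPTY,
    FULL,
    HALF,
    GrainBox,
)
from .stats import (
    DEFAULT_PH_MODEL,
    PHModel,
    PanicleCounts,
    counts_from_grains,
    estimate_ph,
    rssr_optimized,
)
from .tiling import (
    DEFAULT_MIN_AREA_FRACTION,
    TileGrid,
    crop_image,
    cut_annotations,
    to_image_coords,
)
from .voc import AnnotatedImage


@runtime_checkable
class Detector(Protocol):
    """Anything that turns a tile image into grain boxes with confidences."""

    def detect(self, tile_image: np.ndarray) -> list[GrainBox]: ...


@dataclass(frozen=True)
class DetectorParams:
    """Tunables of the classical baseline detector.

    ``min_area``/``max_area`` bound plausible grain components in px²;
    ``border_margin`` (px) defines "touching the tile border";
    ``center_radius`` (px) is the disk around the component centroid whose
    mean intensity is compared with the whole-component mean to separate
    center-bright full grains from crack-dark empty grains;
    ``min_contrast`` is the minimum gray-level spread below which a tile is
    treated as background-only.
    """

    min_area: int = 40
    max_area: int = 5000
    border_margin: int = 1
    center_radius: float = 2.5
    min_contrast: float = 30.0
    margin_scale: float = 100.0  # maps the classifier margin to confidence


class ThresholdDetector:
    """Classical detector for dark-background synthetic panicle tiles."""

    def __init__(self, params: DetectorParams | None = None):
        self.params = params or DetectorParams()

    def detect(self, tile_image: np.ndarray) -> list[GrainBox]:
        p = self.params
        gray = _to_gray(tile_image)
        h, w = gray.shape
        if gray.max() - gray.min() < p.min_contrast:
            return []  # background-only tile
        # Otsu separates background from grain pixels; the floor at 35% of
        # the tile maximum keeps dim stems out when grains dominate.
        thr = max(float(threshold_otsu(gray)), 0.35 * float(gray.max()))
        mask = gray > thr
        labels = cc_label(mask, connectivity=2)
        out: list[GrainBox] = []
        for region in regionprops(labels, intensity_image=gray):
            if not (p.min_area <= region.area <= p.max_area):
                continue
            minr, minc, maxr, maxc = region.bbox
            box = Box(float(minc), float(minr), float(maxc), float(maxr))
            touches_border = (
                minc <= p.border_margin
                or minr <= p.border_margin
                or maxc >= w - p.border_margin
                or maxr >= h - p.border_margin
            )
            score = _center_margin(region, gray, p.center_radius)
            confidence = float(np.clip(0.5 + abs(score) / p.margin_scale, 0.5, 1.0))
            if touches_border:
                out.append(GrainBox(box, HALF, confidence))
            elif score >= 0:
                out.append(GrainBox(box, FULL, confidence))
            else:
                out.append(GrainBox(box, EMPTY, confidence))
        return out


def _to_gray(image: np.ndarray) -> np.ndarray:
    if not isinstance(image, np.ndarray) or image.ndim not in (2, 3):
        raise TypeError("expected a 2-D grayscale or 3-D RGB image array")
    if image.ndim == 3:
        return image[..., :3].astype(float).mean(axis=-1)
    return image.astype(float)


def _center_margin(region, gray: np.ndarray, radius: float) -> float:
    """Mean intensity near the centroid minus the component mean.

    Positive for center-bright (full) grains, negative when the centroid
    sits on the dark medial crack of an empty grain.  The centroid disk is
    sampled on the raw image, not on the component's own pixels: a crack
    dark enough to fall below the foreground threshold is excluded from
    the component mask, and sampling only member pixels would then miss
    exactly the evidence that distinguishes an empty grain.
    """
    cy, cx = region.centroid
    h, w = gray.shape
    r = int(np.ceil(radius))
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    center_mean = gray[yy[disk], xx[disk]].mean() if disk.any() else gray[int(cy), int(cx)]
    coords = region.coords  # (row, col) pairs
    region_mean = gray[coords[:, 0], coords[:, 1]].mean()
    return float(center_mean - region_mean)


class PassthroughDetector:
    """Ground-truth passthrough: replays tile annotations as detections.

    Valid under the detector interface; used as the oracle detector in
    end-to-end tests and available to users for pipeline dry-runs.
    Construct per image with the tiles from :func:`tiling.cut_annotations`.
    """

    def __init__(self, tiles):
        self._tiles = list(tiles)
        self._i = 0

    def detect(self, tile_image: np.ndarray) -> list[GrainBox]:
        tile = self._tiles[self._i]
        self._i += 1
        return list(tile.grains)


def tally_image_detections(
    detections: Iterable[GrainBox],
) -> PanicleCounts:
    """Aggregate merged image-coordinate detections into counts."""
    labels = []
    subtypes = []
    for d in detections:
        labels.append(d.label.value)
        subtypes.append(d.category.half_subtype.value)
    return counts_from_grains(labels, subtypes)


def detections_to_table(records: Iterable[tuple[str, tuple[int, int], GrainBox]]):
    """Flatten (image_id, (col, row), grain) records into an exchange table.

    This CSV-ready table (image_id, tile col/row, category, subtype,
    confidence, tile-local corners) is the adapter point for external
    detectors: anything that can produce it can feed the evaluator and the
    rate pipeline.
    """
    import pandas as pd

    rows = []
    for image_id, (col, row), g in records:
        rows.append(
            {
                "image_id": image_id,
                "tile_col": col,
                "tile_row": row,
                "category": g.label.value,
                "half_subtype": g.category.half_subtype.value,
                "confidence": g.confidence,
                "x_min": g.box.x_min,
                "y_min": g.box.y_min,
                "x_max": g.box.x_max,
                "y_max": g.box.y_max,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "image_id", "tile_col", "tile_row", "category", "half_subtype",
            "confidence", "x_min", "y_min", "x_max", "y_max",
        ],
    )


def detections_from_table(table) -> list[tuple[str, tuple[int, int], GrainBox]]:
    """Inverse of :func:`detections_to_table`."""
    from .geometry import GrainCategory, GrainLabel, HalfSubtype

    out = []
    for rec in table.to_dict("records"):
        category = GrainCategory(
            GrainLabel(rec["category"]), HalfSubtype(rec["half_subtype"])
        )
        grain = GrainBox(
            Box(rec["x_min"], rec["y_min"], rec["x_max"], rec["y_max"]),
            category,
            float(rec["confidence"]),
        )
        out.append((rec["image_id"], (int(rec["tile_col"]), int(rec["tile_row"])), grain))
    return out


def run_pipeline(
    inputs: Sequence[tuple[str, np.ndarray | None, AnnotatedImage | None]],
    grid_shape: tuple[int, int] = (6, 4),
    detector: Detector | None = None,
    ph_model: PHModel = DEFAULT_PH_MODEL,
    min_area_fraction: float = DEFAULT_MIN_AREA_FRACTION,
    manual: Mapping[str, tuple[int, int]] | None = None,
):
    """Tile, detect, merge and score every image; one row per image.

    ``inputs`` is a sequence of ``(image_id, image, annotation)``.  With a
    ``detector``, each image is cropped on the grid and the detector runs
    per tile (the image array is required).  Without one, the ground-truth
    annotations are passed through the same tiling instead — the oracle
    detector.  Detected tile boxes are mapped back to image coordinates,
    tallied into NF/NE/NH, and scored:

    * ``ratio1``  = NF / (NF + NE) over whole (uncut) detections,
    * ``ph``      = clamped linear prior evaluated at ratio1,
    * ``rssr``    = (NF + ph*NH/2) / (NF + NE + NH/2).

    ``manual`` optionally maps image_id to (NFt, NEt) manual counts, adding
    a traditional-rate column.  Returns a pandas DataFrame.
    """
    import pandas as pd

    from .stats import ManualCounts, UndefinedRateError, rssr_traditional

    rows = []
    for image_id, image, annotated in inputs:
        if detector is None:
            if annotated is None:
                raise ValueError(f"{image_id}: need annotations for passthrough run")
            grid = TileGrid(annotated.width, annotated.height, *grid_shape)
            tiles = cut_annotations(annotated, grid, min_area_fraction)
            merged = [
                to_image_coords(tile, g) for tile in tiles for g in tile.grains
            ]
        else:
            if image is None:
                raise ValueError(f"{image_id}: need the image array to run a detector")
            grid = TileGrid(image.shape[1], image.shape[0], *grid_shape)
            tile_images = crop_image(image, grid)
            frames = grid.frames()
            merged = []
            for (idx, frame), tile_img in zip(frames, tile_images):
                for det in detector.detect(tile_img):
                    merged.append(det.translate(frame.x_min, frame.y_min))
        counts = tally_image_detections(merged)
        if counts.NF + counts.NE > 0:
            r1 = counts.NF / (counts.NF + counts.NE)
            ph = estimate_ph(r1, ph_model)
            rate = rssr_optimized(counts, ph)
        else:
            r1 = ph = rate = float("nan")
        row = {
            "image_id": image_id,
            "NF": counts.NF,
            "NE": counts.NE,
            "NH": counts.NH,
            "ratio1": r1,
            "ph": ph,
            "rssr": rate,
        }
        if manual and image_id in manual:
            nft, net = manual[image_id]
            try:
                row["rssr_manual"] = rssr_traditional(ManualCounts(nft, net))
            except UndefinedRateError:
                row["rssr_manual"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
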