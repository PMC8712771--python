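"""Synthetic panicle scenes with exact bounding-box ground truth.

Emulates the darkroom capture setup the pipeline targets: a near-black
light-absorbing background, one to four panicles per image, and elongated
grain blobs strung along smoothly curving panicle stems.  Full grains are
rendered with raised, center-bright radial shading; empty grains are flat
with a dark medial crack along the long axis — the two appearance cues a
grain classifier can exploit.  A gentle top-lit brightness ramp models the
single overhead light source.

Grains are shaded ellipses, not photoreal textures: the pipeline under
test consumes boxes and counts, and box-level geometry (including grains
that happen to cross tile boundaries) is what matters downstream.

Everything is driven by one integer seed; identical configurations give
bit-identical images and annotations.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .geometry import Box, GrainBox, GrainCategory, GrainLabel, iou
from .stats import PanicleCounts
from .voc import AnnotatedImage, write_voc


class PackingError(RuntimeError):
    """Could not place a grain under the pairwise-overlap cap."""


@dataclass(frozen=True)
class GrainSpec:
    """Geometry + category of one rendered grain (axis lengths are semi-axes)."""

    cx: float
    cy: float
    half_length: float
    half_width: float
    angle: float  # radians, 0 = horizontal major axis
    label: GrainLabel

    def bounding_box(self) -> Box:
        """Tight axis-aligned box of the rotated ellipse, on integer pixel corners."""
        ex = np.hypot(self.half_length * np.cos(self.angle), self.half_width * np.sin(self.angle))
        ey = np.hypot(self.half_length * np.sin(self.angle), self.half_width * np.cos(self.angle))
        return Box(
            float(np.floor(self.cx - ex)),
            float(np.floor(self.cy - ey)),
            float(np.ceil(self.cx + ex)),
            float(np.ceil(self.cy + ey)),
        )


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic panicle scene.

    Defaults are a quarter-linear-scale desk version of the 4032x3024
    capture geometry (1008x756 canvas, so the standard 6x4 grid gives
    168x189 tiles), with per-panicle grain counts and seed setting rates in
    the range observed on real panicles.
    """

    image_w: int = 1008
    image_h: int = 756
    n_panicles: int = 2
    grains_per_panicle: tuple[int, int] = (40, 80)
    true_rssr: float = 0.85
    grain_length: tuple[float, float] = (18.0, 26.0)  # full major axis, px
    grain_width: tuple[float, float] = (7.0, 11.0)  # full minor axis, px
    background_level: float = 12.0
    crack_contrast: float = 60.0
    max_overlap_iou: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.true_rssr <= 1.0):
            raise ValueError("true_rssr must be in [0, 1]")
        if not (1 <= self.n_panicles <= 4):
            raise ValueError("n_panicles must be between 1 and 4")
        if self.image_w <= 0 or self.image_h <= 0:
            raise ValueError("image dimensions must be positive")
        lo, hi = self.grains_per_panicle
        if lo < 0 or hi < lo:
            raise ValueError("grains_per_panicle must be a nondecreasing pair")


# rendering intensity model (gray levels before the light ramp and tint)
_FULL_BASE = 110.0
_FULL_PEAK = 120.0  # added at the grain center, Gaussian falloff
_EMPTY_BASE = 150.0
_STEM_LEVEL = 38.0
_RAMP = 0.05  # top-lit: intensity falls by this fraction from top to bottom


def _sample_grain_specs(
    config: SceneConfig, rng: np.random.Generator
) -> tuple[list[GrainSpec], list[int]]:
    """Place grains along panicle stems under the pairwise box-IOU cap.

    Returns the specs (contiguous per panicle) and the per-panicle counts.
    """
    w, h = config.image_w, config.image_h
    margin = config.grain_length[1]
    specs: list[GrainSpec] = []
    boxes: list[Box] = []
    sizes: list[int] = []
    lo, hi = config.grains_per_panicle

    for p in range(config.n_panicles):
        # stem: gentle sinusoid from near the top down through the frame
        x0 = (p + 1) * w / (config.n_panicles + 1) + rng.uniform(-w * 0.04, w * 0.04)
        amp = rng.uniform(0.03, 0.08) * w
        phase = rng.uniform(0, 2 * np.pi)
        tilt = rng.uniform(-0.1, 0.1) * w
        y_top, y_bot = 0.10 * h, 0.92 * h

        n_grains = int(rng.integers(lo, hi + 1))
        sizes.append(n_grains)
        for _ in range(n_grains):
            placed = False
            for _attempt in range(500):
                t = rng.uniform(0.05, 1.0)
                y = y_top + t * (y_bot - y_top)
                x = x0 + amp * np.sin(phase + 3.0 * t * np.pi) + tilt * t
                # branchlet offset away from the stem; the corridor widens as
                # attempts accumulate so dense panicles can still pack
                off = rng.uniform(6.0, 26.0 + 0.2 * _attempt) * rng.choice((-1.0, 1.0))
                ang = rng.uniform(-np.pi / 2, np.pi / 2) * 0.9
                cx = float(np.clip(x + off * np.cos(ang), margin, w - margin))
                cy = float(np.clip(y + off * np.sin(ang) * 0.5, margin, h - margin))
                spec = GrainSpec(
                    cx=cx,
                    cy=cy,
                    half_length=rng.uniform(*config.grain_length) / 2.0,
                    half_width=rng.uniform(*config.grain_width) / 2.0,
                    angle=float(ang + rng.normal(0, 0.3)),
                    label=GrainLabel.FULL
                    if rng.random() < config.true_rssr
                    else GrainLabel.EMPTY,
                )
                box = spec.bounding_box()
                if box.x_min < 0 or box.y_min < 0 or box.x_max > w or box.y_max > h:
                    continue
                if all(iou(box, b) <= config.max_overlap_iou for b in boxes):
                    specs.append(spec)
                    boxes.append(box)
                    placed = True
                    break
            if not placed:
                raise PackingError(
                    f"could not place grain under max_overlap_iou="
                    f"{config.max_overlap_iou} after 300 attempts"
                )
    return specs, sizes


def render_scene(
    specs: list[GrainSpec],
    config: SceneConfig,
    rng: np.random.Generator,
    stems: bool = True,
) -> np.ndarray:
    """Render grains (and optional dim stems) onto the dark canvas.

    Returns an RGB uint8 array of shape (image_h, image_w, 3).
    """
    w, h = config.image_w, config.image_h
    gray = np.full((h, w), config.background_level, dtype=float)
    gray += rng.normal(0.0, 1.5, size=gray.shape)  # sensor noise on black cloth

    if stems and specs:
        # dim stems: thin vertical-ish polylines under the grains
        ys = np.arange(int(0.10 * h), int(0.92 * h))
        for p in range(config.n_panicles):
            x0 = (p + 1) * w / (config.n_panicles + 1)
            xs = (x0 + 0.05 * w * np.sin(2 * np.pi * ys / h)).astype(int)
            xs = np.clip(xs, 1, w - 2)
            for dx in (-1, 0, 1):
                gray[ys, xs + dx] = np.maximum(gray[ys, xs + dx], _STEM_LEVEL)

    for spec in specs:
        box = spec.bounding_box()
        x0, y0 = int(box.x_min), int(box.y_min)
        x1, y1 = int(box.x_max), int(box.y_max)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dx = xx - spec.cx
        dy = yy - spec.cy
        c, s = np.cos(spec.angle), np.sin(spec.angle)
        u = dx * c + dy * s  # along major axis
        v = -dx * s + dy * c
        r2 = (u / spec.half_length) ** 2 + (v / spec.half_width) ** 2
        mask = r2 <= 1.0
        patch = gray[y0:y1, x0:x1]
        if spec.label is GrainLabel.FULL:
            shade = _FULL_BASE + _FULL_PEAK * np.exp(-1.3 * r2)
            patch[mask] = np.maximum(patch[mask], shade[mask])
        else:
            flat = np.full_like(r2, _EMPTY_BASE)
            crack = (np.abs(v) <= max(1.0, 0.12 * spec.half_width * 2)) & (
                np.abs(u) <= 0.85 * spec.half_length
            )
            flat[crack] -= config.crack_contrast
            patch[mask] = np.maximum(patch[mask], flat[mask])
        gray[y0:y1, x0:x1] = patch

    # single top light source: brightness ramps down toward the bottom
    ramp = 1.0 - _RAMP * (np.arange(h) / max(h - 1, 1))
    gray *= ramp[:, None]
    gray = np.clip(gray, 0, 255)

    rgb = np.stack([gray, gray * 0.92, gray * 0.55], axis=-1)
    return np.clip(rgb, 0, 255).astype(np.uint8)


def generate_scene(
    config: SceneConfig,
) -> tuple[np.ndarray, AnnotatedImage, list[PanicleCounts]]:
    """Generate one scene: image, exact annotations, per-panicle truth counts.

    Categories are Bernoulli(true_rssr) per grain; ground-truth boxes are
    the tight bounding boxes of the rendered ellipses.  Output is
    bit-identical for identical configurations.
    """
    rng = np.random.default_rng(config.seed)
    specs, sizes = _sample_grain_specs(config, rng)
    image = render_scene(specs, config, rng)

    grains = tuple(
        GrainBox(spec.bounding_box(), GrainCategory(spec.label), confidence=1.0)
        for spec in specs
    )
    annotated = AnnotatedImage(
        image_id=f"scene_{config.seed}",
        width=config.image_w,
        height=config.image_h,
        grains=grains,
    )

    # per-panicle truth: specs are emitted panicle by panicle in order
    truth: list[PanicleCounts] = []
    i = 0
    for n in sizes:
        chunk = specs[i : i + n]
        i += n
        nf = sum(1 for s in chunk if s.label is GrainLabel.FULL)
        truth.append(PanicleCounts(NF=nf, NE=len(chunk) - nf, NH=0, NFH=0, NEH=0))
    return image, annotated, truth


def per_image_seed(master_seed: int, index: int) -> int:
    """Deterministic sub-seed for image ``index`` from one master seed."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_dataset(config: SceneConfig, n_images: int, out_dir: str | os.PathLike):
    """Write ``n_images`` scenes (PNG + VOC XML) plus a truth manifest CSV.

    Per-image seeds derive deterministically from ``config.seed``; the
    manifest records image_id, seed, true NF/NE and the true seed setting
    rate.  Returns the manifest as a pandas DataFrame.
    """
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n_images):
        cfg = replace(config, seed=per_image_seed(config.seed, i))
        image, annotated, truth = generate_scene(cfg)
        image_id = f"scene_{i:03d}"
        annotated = AnnotatedImage(image_id, annotated.width, annotated.height, annotated.grains)
        Image.fromarray(image).save(out / f"{image_id}.png")
        write_voc(annotated, out / f"{image_id}.xml")
        nf = sum(t.NF for t in truth)
        ne = sum(t.NE for t in truth)
        rows.append(
            {
                "image_id": image_id,
                "seed": cfg.seed,
                "true_nf": nf,
                "true_ne": ne,
                "true_rssr": nf / (nf + ne) if nf + ne > 0 else float("nan"),
            }
        )
    manifest = pd.DataFrame(
        rows, columns=["image_id", "seed", "true_nf", "true_ne", "true_rssr"]
    )
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
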