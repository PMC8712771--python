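"""Published 10-panicle validation table used as reference input.

A released manual-vs-algorithm comparison on ten rice panicle images:
per-panicle full and empty grain counts obtained by hand and by the
automated detection pipeline, plus the seed setting rate the pipeline
reported for each image (in percent).  These numbers are inputs — the
accuracy and rate arithmetic in :mod:`rssr.evaluation` and
:mod:`rssr.stats` is validated against the per-sample accuracies and
column means that accompany them.

The algorithm's printed per-image rates are carried verbatim because they
are not recoverable from the printed counts alone (the pipeline's internal
half-grain counts were not published).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ValidationSample:
    """One panicle image: manual vs algorithm counts and the algorithm's rate."""

    label: int
    manual_full: int
    algo_full: int
    manual_empty: int
    algo_empty: int
    algo_rssr_pct: float


VALIDATION_SAMPLES: tuple[ValidationSample, ...] = (
    ValidationSample(1, 64, 64, 35, 34, 64.89),
    ValidationSample(2, 88, 86, 39, 40, 68.53),
    ValidationSample(3, 117, 119, 27, 27, 81.55),
    ValidationSample(4, 83, 82, 21, 20, 80.23),
    ValidationSample(5, 97, 99, 15, 16, 86.18),
    ValidationSample(6, 141, 146, 9, 10, 93.65),
    ValidationSample(7, 54, 55, 20, 20, 73.08),
    ValidationSample(8, 64, 66, 5, 5, 92.69),
    ValidationSample(9, 52, 55, 3, 2, 95.79),
    ValidationSample(10, 89, 91, 12, 11, 88.98),
)

#: Image geometry of the capture setup the tiling defaults were derived
#: from: 4032x3024 source images cut on a 6x4 grid (24 tiles per image).
SOURCE_IMAGE_W = 4032
SOURCE_IMAGE_H = 3024
DEFAULT_TILES_X = 6
DEFAULT_TILES_Y = 4
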