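"""Detection and counting evaluation.

Detection quality is scored by greedy confidence-ordered one-to-one
matching against ground truth at an IOU threshold (0.5 headline; 0.25 and
0.75 variants), yielding TP/FP/FN, precision/recall/F1, and per-class
average precision summed over the raw precision-recall staircase:

    AP = sum_k Precision(k) * (Recall(k) - Recall(k-1)),   Recall(0) = 0

with no interpolation by default (an all-point-interpolated variant is
available behind a flag).  mAP is the unweighted mean of per-class APs.

Counting quality uses MAE, MSE, RMSE = sqrt(MSE) and the agreement index

    r = 1 - sum (t_i - c_i)^2 / sum (t_i - tbar)^2

which is a coefficient-of-determination form, not a Pearson correlation;
both interpretations are common under the name "correlation coefficient",
so this module names it ``r_eq`` and leaves Pearson to scipy.

Per-sample accuracy of a count or a rate is the symmetric ratio
``100 * min / max`` of the two values, i.e. the smaller as a percentage of
the larger; it is <= 100 and symmetric in its arguments.  (The count and
rate accuracy measures were reconstructed from a published 10-panicle
validation table; the min/max form reproduces all 30 printed cells.)

Undefined quantities (zero denominators) are reported as NaN markers,
never as silent zeros, except F1 which is defined as 0 when
precision + recall = 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .geometry import Box, GrainBox, iou


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class MatchSummary:
    """Confusion counts of one matching run at one IOU threshold."""

    TP: int
    FP: int
    FN: int
    iou_threshold: float

    @property
    def n_gt(self) -> int:
        return self.TP + self.FN


def match_detections(
    dets: Sequence[GrainBox],
    gts: Sequence[Box | GrainBox],
    iou_threshold: float = 0.5,
) -> tuple[MatchSummary, list[bool]]:
    """Greedily match detections to ground truth, single class per call.

    Detections are processed in descending confidence (ties broken by input
    order); each claims the still-unmatched ground truth of highest
    IOU >= threshold, else counts as a false positive.  Ground truths left
    unmatched are false negatives.

    Returns the summary plus per-detection TP flags in descending-confidence
    order (the input order for :func:`average_precision`).
    """
    if not (0.0 < iou_threshold <= 1.0):
        raise EvaluationError(f"iou_threshold must be in (0, 1], got {iou_threshold}")
    gt_boxes = [g.box if isinstance(g, GrainBox) else g for g in gts]
    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    matched = [False] * len(gt_boxes)
    flags: list[bool] = []
    for i in order:
        best_j, best_iou = -1, 0.0
        for j, gt in enumerate(gt_boxes):
            if matched[j]:
                continue
            v = iou(dets[i].box, gt)
            if v >= iou_threshold and v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            matched[best_j] = True
            flags.append(True)
        else:
            flags.append(False)
    tp = sum(flags)
    return (
        MatchSummary(TP=tp, FP=len(flags) - tp, FN=len(gt_boxes) - tp,
                     iou_threshold=iou_threshold),
        flags,
    )


def precision_recall_f1(s: MatchSummary) -> tuple[float, float, float]:
    """(precision, recall, F1); NaN marks an undefined component."""
    precision = s.TP / (s.TP + s.FP) if s.TP + s.FP > 0 else math.nan
    recall = s.TP / (s.TP + s.FN) if s.TP + s.FN > 0 else math.nan
    if math.isnan(precision) or math.isnan(recall):
        f1 = math.nan
    elif precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def average_precision(
    flags: Sequence[bool], n_gt: int, interpolated: bool = False
) -> float:
    """Average precision over a ranked TP/FP flag list.

    ``flags`` must be in descending-confidence order.  The default is the
    raw staircase sum (no interpolation); ``interpolated=True`` applies
    all-point interpolation (precision envelope from the right).
    """
    if n_gt < 1:
        raise EvaluationError("n_gt must be >= 1 for a defined AP")
    tp_cum = np.cumsum(np.asarray(flags, dtype=float))
    k = np.arange(1, len(tp_cum) + 1)
    precision = tp_cum / k
    recall = tp_cum / n_gt
    if interpolated:
        precision = np.maximum.accumulate(precision[::-1])[::-1]
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum(precision * (recall - prev_recall)))


def mean_ap(per_class_ap: Mapping[str, float]) -> float:
    """Unweighted mean of per-class APs; NaN entries (no ground truth) excluded."""
    defined = {k: v for k, v in per_class_ap.items() if not math.isnan(v)}
    if len(defined) < len(per_class_ap):
        skipped = sorted(set(per_class_ap) - set(defined))
        warnings.warn(f"classes without defined AP excluded from mAP: {skipped}",
                      stacklevel=2)
    if not defined:
        raise EvaluationError("no class has a defined AP")
    return float(np.mean(list(defined.values())))


def count_accuracy(t_count: float, c_count: float) -> float:
    """Percent agreement of two counts: ``100 * min / max``; 100 when both zero."""
    if t_count < 0 or c_count < 0:
        raise EvaluationError("counts must be nonnegative")
    if t_count == 0 and c_count == 0:
        return 100.0
    return 100.0 * min(t_count, c_count) / max(t_count, c_count)


def rate_accuracy(manual_rate_pct: float, algo_rate_pct: float) -> float:
    """Percent agreement of two rates (in percent): ``100 * min / max``."""
    if manual_rate_pct <= 0:
        raise EvaluationError("manual rate must be positive")
    if algo_rate_pct < 0:
        raise EvaluationError("rates must be nonnegative")
    return 100.0 * min(manual_rate_pct, algo_rate_pct) / max(manual_rate_pct, algo_rate_pct)


@dataclass(frozen=True)
class CountComparison:
    """Ground-truth vs inferred count for one image."""

    t: float
    c: float

    def __post_init__(self) -> None:
        if self.t < 0 or self.c < 0:
            raise EvaluationError("counts must be nonnegative")


@dataclass(frozen=True)
class ErrorStats:
    """Counting-error summary; ``r_eq`` is NaN when the truth is constant."""

    mae: float
    mse: float
    rmse: float
    r_eq: float


def evaluate_dataset(
    dets_by_image: Mapping[str, Sequence[GrainBox]],
    gts_by_image: Mapping[str, Sequence[GrainBox]],
    iou_thresholds: Sequence[float] = (0.25, 0.5, 0.75),
    classes: Sequence[str] = ("full", "empty", "half"),
):
    """Per-class P/R/F1/AP at each IOU threshold over a set of images.

    Matching is done per image and per class; the TP/FP flags are then
    pooled across images in global descending-confidence order for AP.
    Returns a pandas DataFrame with one row per (iou_threshold, class) plus
    an mAP row per threshold.
    """
    import pandas as pd

    rows = []
    image_ids = sorted(set(dets_by_image) | set(gts_by_image))
    for thr in iou_thresholds:
        per_class_ap: dict[str, float] = {}
        for cls in classes:
            tp = fp = fn = 0
            scored: list[tuple[float, bool]] = []
            n_gt = 0
            for img in image_ids:
                dets = [d for d in dets_by_image.get(img, []) if d.label.value == cls]
                gts = [g for g in gts_by_image.get(img, []) if g.label.value == cls]
                summary, flags = match_detections(dets, gts, thr)
                tp += summary.TP
                fp += summary.FP
                fn += summary.FN
                n_gt += len(gts)
                confs = sorted((d.confidence for d in dets), reverse=True)
                scored.extend(zip(confs, flags))
            scored.sort(key=lambda t: -t[0])
            pooled_flags = [f for _, f in scored]
            ap = average_precision(pooled_flags, n_gt) if n_gt > 0 else math.nan
            per_class_ap[cls] = ap
            p, r, f1 = precision_recall_f1(
                MatchSummary(TP=tp, FP=fp, FN=fn, iou_threshold=thr)
            )
            rows.append(
                {"iou_threshold": thr, "class": cls, "TP": tp, "FP": fp, "FN": fn,
                 "precision": p, "recall": r, "f1": f1, "ap": ap}
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                map_value = mean_ap(per_class_ap)
            except EvaluationError:
                map_value = math.nan
        rows.append(
            {"iou_threshold": thr, "class": "mAP", "TP": None, "FP": None,
             "FN": None, "precision": None, "recall": None, "f1": None,
             "ap": map_value}
        )
    return pd.DataFrame(rows)


def error_stats(comparisons: Sequence[CountComparison]) -> ErrorStats:
    """MAE, MSE, RMSE = sqrt(MSE), and the 1 - SSres/SStot agreement index."""
    if len(comparisons) < 1:
        raise EvaluationError("need at least one comparison")
    t = np.array([c.t for c in comparisons], dtype=float)
    c = np.array([c.c for c in comparisons], dtype=float)
    mae = float(np.mean(np.abs(t - c)))
    mse = float(np.mean((t - c) ** 2))
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    r_eq = 1.0 - float(np.sum((t - c) ** 2)) / ss_tot if ss_tot > 0 else math.nan
    return ErrorStats(mae=mae, mse=mse, rmse=math.sqrt(mse), r_eq=r_eq)
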