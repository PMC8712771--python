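"""Seed-setting-rate estimators and the half-grain prior model.

The seed setting rate of a panicle is the fraction of its grains that are
full (filled):

    RSSR_t = NF_t / (NF_t + NE_t)                         (traditional)

After grid tiling, grains cut by tile boundaries appear as ``half`` boxes.
Each interior cut produces two half boxes, so ``NH/2`` estimates the
number of cut grains, and the corrected estimator is

    RSSR_a = (NF + PH * NH/2) / (NF + NE + NH/2)

where ``PH`` is the prior probability that a cut grain is full.  PH is
supplied by a linear model on the full fraction among uncut grains,

    Ratio1 = NF / (NF + NE)        Ratio2 = NFH / (NFH + NEH)
    PH = slope * Ratio1 + intercept,   clamped to [0, 1]

with default coefficients slope = 0.797, intercept = 0.1972 (Pearson
correlation 0.8327 in the calibration that produced them).  The model may
be refit from (Ratio1, Ratio2) pairs by ordinary least squares; a
two-sample Kolmogorov–Smirnov test is provided to check that the two
ratio samples are distributionally consistent, the premise of using
Ratio2 as a linear function of Ratio1.

Rates are fractions in [0, 1] internally and formatted as percentages
only in reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps


class UndefinedRateError(ZeroDivisionError):
    """A rate/ratio whose denominator is zero."""


class DegenerateFitError(ValueError):
    """Not enough spread in the predictor to fit the linear prior."""


@dataclass(frozen=True)
class ManualCounts:
    """Full/empty grain counts from traditional (manual) counting."""

    NFt: int
    NEt: int

    def __post_init__(self) -> None:
        if self.NFt < 0 or self.NEt < 0:
            raise ValueError("counts must be nonnegative")


@dataclass(frozen=True)
class PanicleCounts:
    """Aggregated detection counts for one image or panicle.

    ``NH`` is the number of half *boxes* at tile level, before the ``NH/2``
    halving.  ``NFH``/``NEH`` split NH by provenance (full/empty before the
    cut); they are known for ground truth and usually unknown for detector
    output.
    """

    NF: int
    NE: int
    NH: int = 0
    NFH: int | None = None
    NEH: int | None = None

    def __post_init__(self) -> None:
        for name in ("NF", "NE", "NH"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if (self.NFH is None) != (self.NEH is None):
            raise ValueError("NFH and NEH must be given together")
        if self.NFH is not None:
            if self.NFH < 0 or self.NEH < 0:
                raise ValueError("NFH/NEH must be nonnegative")
            if self.NFH + self.NEH != self.NH:
                raise ValueError(
                    f"NFH + NEH = {self.NFH + self.NEH} must equal NH = {self.NH}"
                )


@dataclass(frozen=True)
class RatioPair:
    """(full fraction among whole grains, full fraction among half grains)."""

    ratio1: float
    ratio2: float

    def __post_init__(self) -> None:
        for name in ("ratio1", "ratio2"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class PHModel:
    """Linear prior for the probability that a cut (half) grain is full."""

    slope: float = 0.797
    intercept: float = 0.1972
    correlation: float | None = None

    def __post_init__(self) -> None:
        if self.correlation is not None and not (-1.0 <= self.correlation <= 1.0):
            raise ValueError(f"correlation must be in [-1, 1], got {self.correlation}")


#: The published default prior coefficients.
DEFAULT_PH_MODEL = PHModel()


def rssr_traditional(m: ManualCounts) -> float:
    """Traditional seed setting rate ``NFt / (NFt + NEt)``, as a fraction."""
    total = m.NFt + m.NEt
    if total == 0:
        raise UndefinedRateError("NFt + NEt = 0: seed setting rate undefined")
    return m.NFt / total


def ratios(c: PanicleCounts) -> RatioPair:
    """Full fractions among whole grains (ratio1) and among half grains (ratio2).

    Requires ``NF + NE > 0`` and known ``NFH``/``NEH`` with positive sum.
    """
    if c.NF + c.NE == 0:
        raise UndefinedRateError("NF + NE = 0: ratio1 undefined")
    if c.NFH is None:
        raise UndefinedRateError("NFH/NEH unknown: ratio2 undefined")
    if c.NFH + c.NEH == 0:
        raise UndefinedRateError("NFH + NEH = 0: ratio2 undefined")
    return RatioPair(c.NF / (c.NF + c.NE), c.NFH / (c.NFH + c.NEH))


def ratio1(c: PanicleCounts) -> float:
    """Full fraction among whole (uncut) grains."""
    if c.NF + c.NE == 0:
        raise UndefinedRateError("NF + NE = 0: ratio1 undefined")
    return c.NF / (c.NF + c.NE)


def estimate_ph(r1: float, model: PHModel = DEFAULT_PH_MODEL) -> float:
    """Predicted probability that a half grain is full, clamped to [0, 1]."""
    if not (0.0 <= r1 <= 1.0):
        raise ValueError(f"ratio1 must be in [0, 1], got {r1}")
    return min(1.0, max(0.0, model.slope * r1 + model.intercept))


def rssr_optimized(c: PanicleCounts, ph: float) -> float:
    """Half-grain-corrected seed setting rate.

    ``(NF + ph * NH/2) / (NF + NE + NH/2)``.  With ``NH = 0`` this reduces
    exactly to the traditional rate.  Weakly increasing in NF and ph,
    weakly decreasing in NE, always in [0, 1].
    """
    if not (0.0 <= ph <= 1.0):
        raise ValueError(f"ph must be in [0, 1], got {ph}")
    half_pairs = c.NH / 2.0
    denom = c.NF + c.NE + half_pairs
    if denom == 0:
        raise UndefinedRateError("NF + NE + NH/2 = 0: rate undefined")
    return (c.NF + ph * half_pairs) / denom


def fit_ph_model(pairs: Sequence[RatioPair]) -> PHModel:
    """Ordinary least squares of ratio2 on ratio1, with Pearson correlation.

    Needs at least 3 pairs and non-degenerate ratio1 variance.
    """
    if len(pairs) < 3:
        raise DegenerateFitError(f"need >= 3 ratio pairs, got {len(pairs)}")
    x = np.array([p.ratio1 for p in pairs], dtype=float)
    y = np.array([p.ratio2 for p in pairs], dtype=float)
    if np.ptp(x) < 1e-12:
        raise DegenerateFitError("ratio1 values are constant: slope undefined")
    fit = sps.linregress(x, y)
    return PHModel(slope=float(fit.slope), intercept=float(fit.intercept),
                   correlation=float(fit.rvalue))


def ks_consistency(
    sample_a: Iterable[float], sample_b: Iterable[float]
) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov statistic and asymptotic p-value.

    ``D = sup |ECDF_a - ECDF_b|``.  Used to check that the two ratio
    samples could come from one distribution before pooling them into the
    linear prior.
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def counts_from_grains(labels: Iterable[str], subtypes: Iterable[str] | None = None) -> PanicleCounts:
    """Tally plain labels (and optional half subtypes) into PanicleCounts."""
    nf = ne = nh = 0
    nfh = neh = 0
    subtype_known = True
    subtypes = list(subtypes) if subtypes is not None else None
    for i, label in enumerate(labels):
        if label == "full":
            nf += 1
        elif label == "empty":
            ne += 1
        elif label == "half":
            nh += 1
            st = subtypes[i] if subtypes is not None else "unknown"
            if st == "H-full":
                nfh += 1
            elif st == "H-empty":
                neh += 1
            else:
                subtype_known = False
        else:
            raise ValueError(f"unknown label {label!r}")
    if nh > 0 and subtype_known:
        return PanicleCounts(NF=nf, NE=ne, NH=nh, NFH=nfh, NEH=neh)
    return PanicleCounts(NF=nf, NE=ne, NH=nh)
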