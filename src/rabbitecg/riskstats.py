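"""Risk-stratification statistics.

Sensitivity/specificity of binary arrhythmia predictors, the AAPE x IEIN
bottom-left-quadrant low-risk rule, the pooled two-sample proportion test
for incidences, the Grubbs outlier test, and the Friedewald LDL estimate
``LDL = TC - HDL - TAG/2.2`` (mmol/L).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .entropy import AAPE_THRESHOLD, IEIN_THRESHOLD


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class QuadrantThresholds:
    """Decision thresholds of the entropy quadrant rule (strict <)."""

    aape_threshold: float = AAPE_THRESHOLD
    iein_threshold: float = IEIN_THRESHOLD

    def __post_init__(self):
        if not (math.isfinite(self.aape_threshold)
                and math.isfinite(self.iein_threshold)):
            raise ValueError("thresholds must be finite")


def sensitivity_specificity(counts: ConfusionCounts,
                            ) -> tuple[float, float]:
    """(sensitivity, specificity) = (tp/(tp+fn), tn/(tn+fp)).

    An undefined denominator yields NaN (reported as missing).
    """
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    se = counts.tp / pos if pos else float("nan")
    sp = counts.tn / neg if neg else float("nan")
    return se, sp


def quadrant_low_risk(aape: float, iein_sigma: float,
                      thresholds: QuadrantThresholds | None = None) -> bool:
    """True iff both entropy indices fall strictly inside the bottom-left
    quadrant (``aape < aape_threshold`` and ``iein < iein_threshold``)."""
    thresholds = thresholds or QuadrantThresholds()
    if not (math.isfinite(aape) and math.isfinite(iein_sigma)):
        raise ValueError(
            "missing entropy values: exclude the animal from stratification")
    return (aape < thresholds.aape_threshold
            and iein_sigma < thresholds.iein_threshold)


def calibrate_low_risk_threshold(values, is_low_risk) -> float:
    """Threshold on an entropy index separating low-risk (small) values.

    Chosen on training data as the midpoint of the gap between the highest
    low-risk value and the lowest at-risk value; if the classes overlap,
    just above the highest low-risk value (training sensitivity 1 by
    construction).
    """
    v = np.asarray(values, dtype=float)
    m = np.asarray(is_low_risk, dtype=bool)
    if not m.any() or m.all():
        raise ValueError("both classes are required for calibration")
    hi_low = float(v[m].max())
    lo_risk = float(v[~m].min())
    if lo_risk > hi_low:
        return 0.5 * (hi_low + lo_risk)
    return hi_low * (1.0 + 1e-9) + 1e-12


def two_sample_proportion_test(k1: int, n1: int, k2: int, n2: int,
                               continuity: bool = False,
                               ) -> tuple[float, float]:
    """Pooled-proportion z test, two-sided normal p-value.

    ``z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2))`` with the pooled
    ``p = (k1+k2)/(n1+n2)``; an optional Yates continuity correction
    shrinks ``|p1 - p2|`` by ``(1/n1 + 1/n2)/2``.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("group sizes must be >= 1")
        if not 0 <= k <= n:
            raise ValueError("counts must lie in [0, n]")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        return 0.0, 1.0
    diff = p1 - p2
    if continuity:
        corr = 0.5 * (1.0 / n1 + 1.0 / n2)
        diff = math.copysign(max(abs(diff) - corr, 0.0), diff)
    z = diff / se
    p = 2.0 * stats.norm.sf(abs(z))
    return z, p


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value from the t distribution."""
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_test(values, alpha: float = 0.05) -> int | None:
    """Index of the single most extreme outlier, or None.

    ``G = max|x - mean| / sd`` against the t-based critical value; at most
    one outlier per pass (iterate on the reduced sample for more).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Grubbs test needs n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        return None
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    g = dev[idx] / sd
    return idx if g > grubbs_critical(x.size, alpha) else None


def friedewald_ldl(tc: float, hdl: float, tag: float) -> float:
    """Friedewald LDL estimate (mmol/L): ``TC - HDL - TAG/2.2``.

    Emits a warning when the estimate is negative (outside the formula's
    validity range, e.g. high triglycerides).
    """
    if min(tc, hdl, tag) < 0:
        raise ValueError("lipid concentrations must be non-negative")
    ldl = tc - hdl - tag / 2.2
    if ldl < 0:
        warnings.warn("negative Friedewald LDL estimate: formula outside "
                      "its validity range", stacklevel=2)
    return ldl
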