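"""Repolarization metrics: rabbit QTc correction and short-term variability.

The rabbit-specific rate correction is linear in RR and referenced to
RR = 300 ms::

    QTc = QT - 0.175 * (RR - 300)        [all in ms]

so the correction vanishes at the reference cycle length.  Short-term
variability (STV) of repolarization is the mean absolute beat-to-beat
difference of QTc over a window of consecutive first differences, scaled
by sqrt(2) -- the mean orthogonal distance from the identity line of the
Poincare plot::

    STV = sum_n |D[n-1] - D[n]| / (N * sqrt(2))

with ``D`` the per-beat QTc and ``N`` the number of differences (30 by
default, i.e. a 31-beat window).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Slope of the rabbit linear QT/RR correction (ms per ms).
QTC_SLOPE_RABBIT = 0.175
#: Reference RR interval of the correction (ms).
QTC_RR_REF_MS = 300.0


def round_half_up(x):
    """Round half away from zero toward +inf (report-table convention)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


def qtc_rabbit(qt_ms, rr_ms, slope: float = QTC_SLOPE_RABBIT,
               rr_ref_ms: float = QTC_RR_REF_MS):
    """Rate-corrected QT for the rabbit, ``QTc = QT - slope*(RR - rr_ref)``.

    Parameters
    ----------
    qt_ms, rr_ms : float or array-like
        Per-beat (or group-mean) QT and RR intervals in milliseconds.
    slope, rr_ref_ms : float
        Constants of the linear correction; defaults are the rabbit values.

    Returns
    -------
    float or ndarray
        QTc in milliseconds, same shape as the inputs.
    """
    qt = np.asarray(qt_ms, dtype=float)
    rr = np.asarray(rr_ms, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("RR intervals must be positive for the QTc correction")
    out = qt - slope * (rr - rr_ref_ms)
    if out.ndim == 0:
        return float(out)
    return out


def qt_from_qtc(qtc_ms, rr_ms, slope: float = QTC_SLOPE_RABBIT,
                rr_ref_ms: float = QTC_RR_REF_MS):
    """Inverse coupling: the QT that yields ``qtc_ms`` at cycle length ``rr_ms``."""
    qtc = np.asarray(qtc_ms, dtype=float)
    rr = np.asarray(rr_ms, dtype=float)
    out = qtc + slope * (rr - rr_ref_ms)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class StvConfig:
    """Window configuration of the STV statistic.

    ``n_diffs`` consecutive first differences are summed; the denominator is
    ``denominator * sqrt(2)`` and defaults to ``n_diffs`` so the statistic is
    a mean absolute difference.  The strict 30-beat reading (29 differences,
    denominator still 30) is available via ``StvConfig(n_diffs=29,
    denominator=30)``.
    """

    n_diffs: int = 30
    denominator: int | None = None

    def __post_init__(self):
        if self.n_diffs < 2:
            raise ValueError("n_diffs must be >= 2")
        if self.denominator is not None and self.denominator <= 0:
            raise ValueError("denominator must be positive")

    @property
    def denom(self) -> int:
        return self.n_diffs if self.denominator is None else self.denominator


def stv(d_series, n_diffs: int = 30, denominator: int | None = None,
        window: str = "last") -> float:
    """Short-term variability of a QTc series.

    Parameters
    ----------
    d_series : array-like
        Per-beat QTc values (ms).
    n_diffs : int
        Number of consecutive first differences summed (window of
        ``n_diffs + 1`` beats).
    denominator : int, optional
        Denominator of the statistic before the sqrt(2) factor; defaults to
        ``n_diffs``.
    window : {"last", "sliding"}
        "last" evaluates the final window of the series; "sliding" averages
        the statistic over every full window.
    """
    cfg = StvConfig(n_diffs=n_diffs, denominator=denominator)
    d = np.asarray(d_series, dtype=float)
    need = cfg.n_diffs + 1
    if d.size < need:
        raise ValueError(
            f"STV needs at least {need} beats, got {d.size}")
    scale = cfg.denom * math.sqrt(2.0)
    absdiff = np.abs(np.diff(d))
    if window == "last":
        return float(absdiff[-cfg.n_diffs:].sum() / scale)
    if window == "sliding":
        # mean over all contiguous windows of n_diffs differences
        c = np.convolve(absdiff, np.ones(cfg.n_diffs), mode="valid")
        return float(np.mean(c) / scale)
    raise ValueError(f"unknown window mode {window!r}")


def stv_strict30(d_series) -> float:
    """STV over the last 30 beats (29 differences) with denominator 30."""
    return stv(d_series, n_diffs=29, denominator=30)


def phase_summary(records: pd.DataFrame, stv_n_diffs: int = 30,
                  stv_window: str = "last") -> pd.DataFrame:
    """Group/phase interval summary shaped like a report table.

    Parameters
    ----------
    records : DataFrame
        Per-beat rows with columns ``animal, group, phase, rr_ms, qt_ms,
        qtc_ms`` (normal beats only; NaN QT rows are ignored per metric).
    stv_n_diffs : int
        STV window used per animal and phase.

    Returns
    -------
    DataFrame indexed by (group, phase) with mean/SD columns for RR, QT,
    QTc and STV plus formatted "mean ± SD" strings rounded half-up.
    """
    required = {"animal", "group", "phase", "rr_ms", "qt_ms", "qtc_ms"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    rows = []
    for (group, phase), sub in records.groupby(["group", "phase"], sort=False):
        if sub.empty:
            continue
        per_animal = []
        for animal, a in sub.groupby("animal", sort=False):
            qtc = a["qtc_ms"].dropna().to_numpy()
            try:
                s = stv(qtc, n_diffs=stv_n_diffs, window=stv_window)
            except ValueError:
                s = np.nan
            per_animal.append({
                "rr": a["rr_ms"].mean(),
                "qt": a["qt_ms"].mean(),
                "qtc": a["qtc_ms"].mean(),
                "stv": s,
            })
        pa = pd.DataFrame(per_animal)
        row = {"group": group, "phase": phase, "n_animals": len(pa)}
        for name in ("rr", "qt", "qtc", "stv"):
            m = pa[name].mean()
            sd = pa[name].std(ddof=1) if len(pa) > 1 else 0.0
            row[f"{name}_mean"] = m
            row[f"{name}_sd"] = sd
            if np.isfinite(m):
                row[f"{name}_fmt"] = (f"{int(round_half_up(m))} ± "
                                      f"{int(round_half_up(sd))}")
            else:
                row[f"{name}_fmt"] = "n/a"
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no (group, phase) cells in records")
    return out.set_index(["group", "phase"])
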