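"""Frequency-domain heart-rate variability on the unevenly sampled tachogram.

The Lomb-Scargle periodogram estimates the power spectral density of the
RR tachogram directly on the uneven beat times -- no resampling or
interpolation of the tachogram is performed (that is the point of the
estimator).  Band powers integrate the density over the low-frequency
(0.04-0.15 Hz) and high-frequency (0.15-0.40 Hz) ranges; their ratio is
the usual sympathovagal-balance index.  Analysis is conventionally run on
the last five minutes of the baseline recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import lombscargle

from .synth import BeatSeries


@dataclass(frozen=True)
class HrvBands:
    lf_lo: float = 0.04
    lf_hi: float = 0.15
    hf_lo: float = 0.15
    hf_hi: float = 0.40

    def __post_init__(self):
        if not (0 < self.lf_lo < self.lf_hi <= self.hf_lo < self.hf_hi):
            raise ValueError("bands must satisfy 0 < lf_lo < lf_hi <= hf_lo < hf_hi")


@dataclass
class PsdEstimate:
    """PSD on a frequency grid; ``normalization`` records the unit
    convention ("ms2_per_hz" density, or "variance" for the classically
    normalized periodogram)."""

    freq_hz: np.ndarray
    power: np.ndarray
    normalization: str = "ms2_per_hz"

    def __post_init__(self):
        self.freq_hz = np.asarray(self.freq_hz, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freq_hz.size < 2 or np.any(np.diff(self.freq_hz) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < -1e-12):
            raise ValueError("power values must be non-negative")
        self.power = np.clip(self.power, 0.0, None)


def default_freq_grid(lo: float = 0.02, hi: float = 0.50,
                      step: float = 0.005) -> np.ndarray:
    return np.arange(lo, hi + step / 2, step)


def lomb_scargle(beat_times_s, rr_ms, freq_grid=None,
                 normalization: str = "ms2_per_hz",
                 min_beats: int = 30) -> PsdEstimate:
    """Lomb-Scargle periodogram of the RR tachogram.

    The tachogram abscissa is the beat time of the interval's end; the
    series is mean-centred internally.  ``normalization="ms2_per_hz"``
    scales the raw periodogram by ``2*T/n`` so a sinusoidal modulation of
    amplitude A integrates to a band power of about ``A**2/2`` (ms^2);
    ``"variance"`` returns the classically normalized periodogram
    (raw power divided by the series variance).
    """
    t = np.asarray(beat_times_s, dtype=float)
    y = np.asarray(rr_ms, dtype=float)
    if t.size != y.size:
        raise ValueError("beat times and RR series must have equal length")
    if t.size < min_beats:
        raise ValueError(f"at least {min_beats} beats required")
    freqs = np.asarray(default_freq_grid() if freq_grid is None else freq_grid,
                       dtype=float)
    if freqs.size < 2 or np.any(np.diff(freqs) <= 0) or freqs[0] <= 0:
        raise ValueError("degenerate frequency grid")
    yc = y - y.mean()
    raw = lombscargle(t, yc, 2.0 * np.pi * freqs)
    T = t[-1] - t[0]
    n = t.size
    if normalization == "ms2_per_hz":
        power = raw * 2.0 * T / n
    elif normalization == "variance":
        var = yc.var()
        power = raw / (n * var / 2.0) if var > 0 else np.zeros_like(raw)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return PsdEstimate(freqs, power, normalization)


def band_power(psd: PsdEstimate, lo_hz: float, hi_hz: float) -> float:
    """Trapezoidal integral of the PSD over [lo_hz, hi_hz].

    Band edges shared between adjacent bands are counted once on each
    side, so splitting an interval at an interior grid point is additive.
    """
    f = psd.freq_hz
    if lo_hz < f[0] - 1e-12 or hi_hz > f[-1] + 1e-12 or hi_hz <= lo_hz:
        raise ValueError("band outside the grid span or empty")
    m = (f >= lo_hz - 1e-12) & (f <= hi_hz + 1e-12)
    if m.sum() < 2:
        raise ValueError("band contains fewer than 2 grid points")
    return float(np.trapezoid(psd.power[m], f[m]))


def lf_hf_ratio(lf: float, hf: float) -> float:
    """LF/HF ratio; NaN (missing) when HF is not positive."""
    if not np.isfinite(hf) or hf <= 0:
        return float("nan")
    return float(lf / hf)


def baseline_window(series: BeatSeries, minutes: float = 5.0,
                    phase: str = "baseline") -> BeatSeries:
    """Beats of the last ``minutes`` of the given phase, half-open window.

    The phase end is the first beat time of the following phase (or the
    last phase beat time plus its RR).  If the phase is shorter than the
    window the full phase is returned with a warning.
    """
    mask = series.phase_mask(phase)
    if not mask.any():
        raise ValueError(f"series has no beats in phase {phase!r}")
    idx = np.flatnonzero(mask)
    last = idx[-1]
    if last + 1 < series.n_beats:
        end = float(series.beat_time_s[last + 1])
    else:
        end = float(series.beat_time_s[last] + series.rr_ms[last] / 1000.0)
    start = end - minutes * 60.0
    phase_start = float(series.beat_time_s[idx[0]] - series.rr_ms[idx[0]] / 1000.0)
    if start < phase_start - 1e-9:
        warnings.warn(
            f"phase {phase!r} shorter than {minutes} min; using full phase",
            stacklevel=2)
        start = phase_start
    m = mask & (series.beat_time_s >= start) & (series.beat_time_s < end)
    return BeatSeries(series.beat_time_s[m], series.rr_ms[m],
                      series.qt_ms[m], series.label[m], series.phase[m])


def hrv_metrics(beat_times_s, rr_ms, bands: HrvBands | None = None,
                freq_grid=None) -> dict:
    """LF/HF band powers and ratio from a (cleaned) tachogram."""
    bands = bands or HrvBands()
    psd = lomb_scargle(beat_times_s, rr_ms, freq_grid)
    lf = band_power(psd, bands.lf_lo, bands.lf_hi)
    hf = band_power(psd, bands.hf_lo, bands.hf_hi)
    return {"lf": lf, "hf": hf, "lf_hf": lf_hf_ratio(lf, hf),
            "normalization": psd.normalization}
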