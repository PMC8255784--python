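"""Waveform-to-beats stage: R detection, intervals, ectopic-RR cleaning.

R peaks are found with a derivative-threshold detector: the first
difference of a lightly smoothed signal is compared against a fraction of
its maximum magnitude; each threshold crossing is refined to the local
extremum of the raw signal within a short search window, with a refractory
period suppressing duplicate detections.  Ectopic RR intervals (deviation
from the segment-mean RR beyond 20%) are replaced by linear interpolation
between the nearest retained neighbours before spectral HRV analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import LABEL_TDP, EcgWaveform


@dataclass(frozen=True)
class DetectionConfig:
    """Derivative-threshold R detector parameters.

    ``derivative_threshold_frac`` is the fraction of the maximum absolute
    first difference used as crossing threshold; ``refractory_ms`` the
    minimum separation of accepted peaks; ``search_back_ms`` the window
    after a crossing in which the R extremum is located;
    ``smooth_ms`` the moving-average width applied before differencing and
    ``locate_smooth_ms`` the wider one used for sub-beat peak localization
    (noise robustness of the R time at the cost of peak sharpness).
    Defaults suit rabbit rates of 100-200 bpm.
    """

    derivative_threshold_frac: float = 0.4
    refractory_ms: float = 120.0
    search_back_ms: float = 40.0
    smooth_ms: float = 8.0
    locate_smooth_ms: float = 16.0

    def __post_init__(self):
        if not 0.0 < self.derivative_threshold_frac < 1.0:
            raise ValueError("derivative_threshold_frac must be in (0, 1)")
        if self.refractory_ms <= 0:
            raise ValueError("refractory_ms must be positive")


@dataclass(frozen=True)
class CleanedRr:
    """Result of the 20%-rule RR cleaning."""

    rr_ms: np.ndarray
    ectopic_indices: np.ndarray
    n_replaced: int

    def __post_init__(self):
        if self.n_replaced != self.ectopic_indices.size:
            raise ValueError("n_replaced must equal |ectopic_indices|")


def _box_smooth(x: np.ndarray, width_ms: float, fs: float) -> np.ndarray:
    """Zero-phase moving average; odd window length avoids a half-sample shift."""
    w = max(int(round(width_ms / 1000.0 * fs)), 1)
    if w % 2 == 0:
        w += 1
    if w == 1:
        return x
    return np.convolve(x, np.ones(w) / w, mode="same")


def detect_r_peaks(waveform: EcgWaveform,
                   config: DetectionConfig | None = None) -> np.ndarray:
    """Detect R-peak times (s) with the derivative-threshold algorithm.

    Returns an empty array for flat signals (no crossings is not an error).
    """
    config = config or DetectionConfig()
    x = np.asarray(waveform.samples, dtype=float)
    fs = waveform.fs_hz
    if x.size < 3 or np.ptp(x) == 0:
        return np.empty(0)
    xs = _box_smooth(x, config.smooth_ms, fs)
    xl = _box_smooth(x, config.locate_smooth_ms, fs)
    d = np.diff(xs)
    dmax = np.max(np.abs(d))
    if dmax == 0:
        return np.empty(0)
    thr = config.derivative_threshold_frac * dmax
    crossings = np.flatnonzero(np.abs(d) >= thr)
    refr = max(int(round(config.refractory_ms / 1000.0 * fs)), 1)
    search = max(int(round(config.search_back_ms / 1000.0 * fs)), 1)
    peaks: list[int] = []
    for i in crossings:
        if peaks and i - peaks[-1] < refr:
            continue
        j = i + int(np.argmax(np.abs(xl[i:i + search + 1])))
        if peaks and j - peaks[-1] < refr:
            continue
        peaks.append(j)
    return np.asarray(peaks, dtype=float) / fs


def match_peaks(detected_s, truth_s, tol_s: float = 0.002,
                ) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detections to truth: (tp, fp, fn)."""
    det = np.sort(np.asarray(detected_s, dtype=float))
    tru = np.sort(np.asarray(truth_s, dtype=float))
    i = j = tp = 0
    tol_s = tol_s + 1e-9  # absorb float rounding at the exact boundary
    while i < det.size and j < tru.size:
        diff = det[i] - tru[j]
        if abs(diff) <= tol_s:
            tp += 1
            i += 1
            j += 1
        elif diff < 0:
            i += 1
        else:
            j += 1
    return tp, det.size - tp, tru.size - tp


def f1_score(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else float("nan")


def rr_from_peaks(beat_times_s) -> np.ndarray:
    """RR intervals (ms) from beat times: ``rr[n] = 1000*(t[n+1]-t[n])``."""
    t = np.asarray(beat_times_s, dtype=float)
    if t.size < 2:
        raise ValueError("at least 2 beats are required for RR intervals")
    if np.any(np.diff(t) <= 0):
        raise ValueError("beat times must be strictly increasing")
    return np.diff(t) * 1000.0


def clean_rr(rr_ms, threshold_frac: float = 0.20) -> CleanedRr:
    """Flag and replace ectopic RR intervals (single-pass 20% rule).

    Intervals with ``|rr - mean(rr)| / mean(rr) > threshold_frac`` (mean of
    the raw series, one pass) are replaced by linear interpolation between
    the nearest unflagged neighbours; flagged boundary values take the
    nearest retained value.
    """
    rr = np.asarray(rr_ms, dtype=float)
    if rr.size < 3:
        raise ValueError("at least 3 RR intervals are required")
    m = rr.mean()
    if m <= 0:
        raise ValueError("mean RR must be positive")
    flagged = np.abs(rr - m) / m > threshold_frac
    if np.all(flagged):
        raise ValueError("all intervals flagged: no anchor for interpolation")
    out = rr.copy()
    if np.any(flagged):
        idx = np.arange(rr.size)
        out[flagged] = np.interp(idx[flagged], idx[~flagged], rr[~flagged])
    return CleanedRr(rr_ms=out, ectopic_indices=np.flatnonzero(flagged),
                     n_replaced=int(flagged.sum()))


def measure_qt(waveform: EcgWaveform, beat_times_s=None,
               use_fiducials: bool = True) -> np.ndarray:
    """Per-beat QT (ms): ``(t_end - q_onset) * 1000 / fs``.

    When the waveform carries ground-truth fiducials (synthetic data) and
    ``use_fiducials`` is true they take precedence; TdP beats (no Q/T
    fiducials) yield NaN rather than a fabricated value.  Otherwise QT is
    measured from the waveform: Q onset as the point before R where the
    smoothed derivative falls below 10% of the QRS slope, T end by the
    tangent method (maximum T downslope extrapolated to the isoelectric
    baseline); beats where either lands outside the search windows are NaN.
    """
    fs = waveform.fs_hz
    if use_fiducials and waveform.fiducials is not None:
        f = waveform.fiducials
        qt = (f["t_end"].to_numpy(dtype=float)
              - f["q"].to_numpy(dtype=float)) * 1000.0 / fs
        if "label" in f.columns:
            qt = np.where(f["label"].to_numpy() == LABEL_TDP, np.nan, qt)
        return qt
    if beat_times_s is None:
        raise ValueError("beat times required for waveform-based QT")
    x = np.asarray(waveform.samples, dtype=float)
    baseline = float(np.median(x))
    w = max(int(round(0.008 * fs)), 1)
    xs = np.convolve(x, np.ones(w) / w, mode="same")
    d = np.diff(xs)
    t = np.asarray(beat_times_s, dtype=float)
    rr_s = np.diff(t)
    qt = np.full(t.size, np.nan)
    for i, r_t in enumerate(t):
        r_idx = int(round(r_t * fs))
        if not 0 < r_idx < x.size - 2:
            continue
        # Q onset: walk back from the upstroke to where slope dies off
        back = max(int(round(0.040 * fs)), 2)
        lo = max(r_idx - back, 0)
        seg = np.abs(d[lo:r_idx])
        if seg.size == 0 or seg.max() == 0:
            continue
        below = np.flatnonzero(seg < 0.10 * seg.max())
        q_idx = lo + (below[-1] if below.size else 0)
        # T peak search window
        rr_here = rr_s[i] if i < rr_s.size else (rr_s[-1] if rr_s.size else 0.4)
        t_lo = r_idx + int(round(0.060 * fs))
        t_hi = min(r_idx + int(round(min(0.75 * rr_here, 0.35) * fs)), x.size - 2)
        if t_hi - t_lo < 3:
            continue
        t_pk = t_lo + int(np.argmax(np.abs(xs[t_lo:t_hi] - baseline)))
        d_hi = min(t_pk + int(round(0.080 * fs)), d.size)
        if d_hi - t_pk < 2:
            continue
        sign = np.sign(xs[t_pk] - baseline) or 1.0
        k = t_pk + int(np.argmin(sign * d[t_pk:d_hi]))
        slope = d[k]
        if slope == 0:
            continue
        t_end = k + (baseline - xs[k]) / slope
        qt_val = (t_end - q_idx) * 1000.0 / fs
        if 40.0 <= qt_val <= 1000.0 * rr_here:
            qt[i] = qt_val
    return qt
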