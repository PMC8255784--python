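"""Ordinal-pattern irregularity measures of the baseline ECG.

Three related statistics quantify signal (ir)regularity:

* **rePE** -- empirical permutation entropy: the Shannon entropy of the
  distribution of rank patterns of delay-embedded vectors (each embedded
  vector counts once).
* **AAPE** -- amplitude-aware permutation entropy: the same pattern
  distribution, but each embedded vector ``x = (x_1, ..., x_m)``
  contributes the weight

  ``(A/m) * sum_k |x_k|  +  ((1-A)/(m-1)) * sum_k |x_k - x_{k-1}|``

  (mixing coefficient ``A`` between mean amplitude and mean absolute
  difference), the weights being normalized over all vectors before the
  entropy is taken.  AAPE is invariant to positive rescaling of the series
  but, unlike rePE, *not* to general monotone transforms -- that amplitude
  sensitivity is the point.
* **IEIN sigma** -- an SVD-based index of the *temporal development* of
  irregularity: a sliding-window rePE trace is split into blocks, each
  block's trajectory matrix is decomposed by SVD, the singular-value energy
  shares give a block "information exergy" (energy-weighted negentropy of
  the singular spectrum), and sigma is the dispersion of block exergy over
  the record.  Stationary records score near zero; records whose
  irregularity drifts score higher.  This pipeline is a documented
  reconstruction: its contract is sensitivity to temporal irregularity,
  not bit-level identity with any particular prior implementation.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.signal import decimate as _decimate

from .synth import EcgWaveform

#: Published decision thresholds of the low-risk quadrant rule.  They are
#: parameterization-dependent (order, delay, mixing coefficient, sampling
#: rate of the analyzed segment) and are shipped for reproduction of the
#: classification rule, not as universal constants.
AAPE_THRESHOLD = 1.975
IEIN_THRESHOLD = 670.0


@dataclass(frozen=True)
class OrdinalConfig:
    """Embedding order ``m``, delay ``tau``, AAPE mixing ``A``, log base."""

    m: int = 4
    tau: int = 1
    adjustment: float = 0.5
    log_base: float = math.e
    tie_rule: str = "earlier"

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("order m must be >= 2")
        if self.tau < 1:
            raise ValueError("delay tau must be >= 1")
        if not 0.0 <= self.adjustment <= 1.0:
            raise ValueError("adjustment A must lie in [0, 1]")
        if self.log_base <= 1.0:
            raise ValueError("log base must exceed 1")
        if self.tie_rule not in ("earlier",):
            raise ValueError("tie_rule must be 'earlier'")


@dataclass(frozen=True)
class IeinConfig:
    """Windowed-entropy trace and block-SVD parameters of IEIN sigma."""

    window: int = 500
    hop: int = 250
    windows_per_block: int = 8
    energy_keep: float = 0.99
    m: int = 3
    tau: int = 1

    def __post_init__(self):
        if self.window < self.m * self.tau + 1:
            raise ValueError("window must cover at least m*tau + 1 samples")
        if self.hop < 1:
            raise ValueError("hop must be >= 1")
        if self.windows_per_block < 2:
            raise ValueError("windows_per_block must be >= 2")
        if not 0.0 < self.energy_keep <= 1.0:
            raise ValueError("energy_keep must lie in (0, 1]")


@dataclass
class EntropyResult:
    aape: float
    iein_sigma: float
    config: dict = field(default_factory=dict)
    segment_s: tuple[float, float] = (0.0, 0.0)


class SegmentTooShort(ValueError):
    """Raised when no artifact-free segment of the minimum length exists."""


def _factorials(m: int) -> list[int]:
    return [math.factorial(m - 1 - i) for i in range(m)]


def ordinal_pattern(window, tie_rule: str = "earlier") -> int:
    """Lehmer index in [0, m!) of the rank permutation of one window.

    Ties rank by order of occurrence (the earlier sample ranks lower).
    The map is bijective over distinct-valued windows.
    """
    w = np.asarray(window, dtype=float)
    perm = np.argsort(w, kind="stable")
    return int(_lehmer_codes(perm[None, :])[0])


def _lehmer_codes(perms: np.ndarray) -> np.ndarray:
    """Vectorized Lehmer encoding of permutations (rows) to ints."""
    n, m = perms.shape
    fact = _factorials(m)
    codes = np.zeros(n, dtype=np.int64)
    for i in range(m - 1):
        smaller_after = np.sum(perms[:, i + 1:] < perms[:, i:i + 1], axis=1)
        codes += smaller_after * fact[i]
    return codes


def _embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    n = x.size - (m - 1) * tau
    if n < 1:
        raise ValueError(
            f"series too short for order {m}, delay {tau}")
    idx = np.arange(n)[:, None] + np.arange(m)[None, :] * tau
    return x[idx]


def _pattern_distribution(x, config: OrdinalConfig, weighted: bool,
                          ) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    X = _embed(x, config.m, config.tau)
    codes = _lehmer_codes(np.argsort(X, axis=1, kind="stable"))
    nfac = math.factorial(config.m)
    if weighted:
        A = config.adjustment
        w = (A / config.m) * np.abs(X).sum(axis=1)
        if config.m > 1:
            w = w + ((1.0 - A) / (config.m - 1)) * np.abs(
                np.diff(X, axis=1)).sum(axis=1)
        total = w.sum()
        if total == 0:  # all-zero series: all mass on the tie pattern
            p = np.zeros(nfac)
            p[codes[0]] = 1.0
            return p
        acc = np.bincount(codes, weights=w, minlength=nfac)
        return acc / total
    acc = np.bincount(codes, minlength=nfac).astype(float)
    return acc / acc.sum()


def _entropy(p: np.ndarray, base: float) -> float:
    p = p[p > 0]
    h = -float(np.sum(p * np.log(p)))
    return h / math.log(base)


def aape(series, config: OrdinalConfig | None = None,
         return_distribution: bool = False):
    """Amplitude-aware permutation entropy of a series.

    Value lies in ``[0, log(m!)]`` in the configured base; with
    ``return_distribution`` the normalized pattern-weight vector (length
    ``m!``, summing to 1) is returned alongside.
    """
    config = config or OrdinalConfig()
    p = _pattern_distribution(series, config, weighted=True)
    h = _entropy(p, config.log_base)
    return (h, p) if return_distribution else h


def repe(series, config: OrdinalConfig | None = None,
         return_distribution: bool = False):
    """Count-based empirical permutation entropy (each vector weight 1).

    Equals AAPE exactly whenever every embedded vector carries the same
    amplitude weight (e.g. an alternating +/-c series), and is invariant
    under strictly monotone transforms of the series.
    """
    config = config or OrdinalConfig()
    p = _pattern_distribution(series, config, weighted=False)
    h = _entropy(p, config.log_base)
    return (h, p) if return_distribution else h


def windowed_repe_trace(x, config: IeinConfig) -> np.ndarray:
    """Sliding-window empirical permutation entropy trace."""
    x = np.asarray(x, dtype=float)
    ocfg = OrdinalConfig(m=config.m, tau=config.tau)
    starts = range(0, x.size - config.window + 1, config.hop)
    return np.array([repe(x[s:s + config.window], ocfg) for s in starts])


def iein_sigma(series, config: IeinConfig | None = None) -> float:
    """Information-exergy index sigma: dispersion of block exergy.

    Pipeline: (1) sliding-window rePE trace; (2) per block of
    ``windows_per_block`` trace values, a trajectory (Hankel) matrix;
    (3) singular values per block; (4) energy shares
    ``p_i = s_i^2 / sum s_j^2`` over the retained spectrum
    (``energy_keep`` cumulative-energy truncation, never fewer than two
    components); (5) block exergy =
    block energy times the negentropy ``log r + sum p_i log p_i`` of the
    shares; (6) sigma = standard deviation of block exergy across blocks.
    Stationary-irregularity records give sigma near 0.
    """
    config = config or IeinConfig()
    trace = windowed_repe_trace(series, config)
    B = config.windows_per_block
    n_blocks = trace.size // B
    if n_blocks < 2:
        raise ValueError("record too short for two IEIN blocks")
    k = max(B // 2, 2)
    exergies = []
    for b in range(n_blocks):
        block = trace[b * B:(b + 1) * B]
        rows = B - k + 1
        H = np.lib.stride_tricks.sliding_window_view(block, k)[:rows]
        s = np.linalg.svd(H, compute_uv=False)
        energy = float(np.sum(s ** 2))
        if energy == 0:
            exergies.append(0.0)
            continue
        shares = s ** 2 / energy
        csum = np.cumsum(shares)
        r = int(np.searchsorted(csum, config.energy_keep - 1e-12) + 1)
        # keep at least two components: the spread beyond the leading
        # direction is what carries the temporal-development signal
        r = max(min(2, s.size), r)
        p = shares[:r] / shares[:r].sum()
        negent = math.log(r) + float(np.sum(p * np.log(p))) if r > 1 else 0.0
        exergies.append(energy * negent)
    return float(np.std(exergies))


def _decimate_to(x: np.ndarray, fs_hz: float, target_hz: float) -> np.ndarray:
    q = int(round(fs_hz / target_hz))
    if q <= 1:
        return x
    while q > 12:  # cascade large factors for FIR stability
        x = _decimate(x, 2, ftype="fir", zero_phase=True)
        q = (q + 1) // 2
    return _decimate(x, q, ftype="fir", zero_phase=True)


def entropy_for_animal(waveform: EcgWaveform,
                       ordinal: OrdinalConfig | None = None,
                       iein: IeinConfig | None = None,
                       segment_s: tuple[float, float] | None = None,
                       decimate_to_hz: float = 250.0,
                       min_seconds: float = 20.0) -> EntropyResult:
    """AAPE and IEIN sigma of a baseline ECG segment (waveform level).

    The segment is decimated to ``decimate_to_hz`` before analysis so the
    m-sample ordinal windows span morphological features rather than
    quantization noise.  Raises :class:`SegmentTooShort` when the segment
    is shorter than ``min_seconds`` (the animal is then excluded from
    stratification with a recorded reason).
    """
    ordinal = ordinal or OrdinalConfig()
    iein = iein or IeinConfig()
    t0, t1 = segment_s if segment_s is not None else (0.0, waveform.duration_s)
    t1 = min(t1, waveform.duration_s)
    if t1 - t0 < min_seconds:
        raise SegmentTooShort(
            f"segment of {t1 - t0:.1f} s is shorter than the required "
            f"{min_seconds:.0f} s")
    lo = int(t0 * waveform.fs_hz)
    hi = int(t1 * waveform.fs_hz)
    x = _decimate_to(waveform.samples[lo:hi], waveform.fs_hz, decimate_to_hz)
    value = aape(x, ordinal)
    sigma = iein_sigma(x, iein)
    return EntropyResult(
        aape=float(value), iein_sigma=float(sigma),
        config={"ordinal": asdict(ordinal), "iein": asdict(iein),
                "decimate_to_hz": decimate_to_hz},
        segment_s=(float(t0), float(t1)))
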