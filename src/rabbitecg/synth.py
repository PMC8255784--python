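"""Synthetic rabbit-ECG cohort generator.

Emulates the methoxamine-sensitized rabbit torsades-de-pointes (TdP)
protocol: a four-phase drug timeline (baseline, methoxamine, low- and
high-dose I_Kr block), piecewise-stationary beat series whose RR/QT
statistics mirror the three experimental groups (young control YC, adult
control AC, cholesterol-fed CH), injection of ectopic beats (single beats,
runs of 2-4, bigeminy) and TdP episodes with ground truth, and rendering of
PQRST waveforms with per-beat fiducials.  Every downstream stage of the
analysis pipeline can therefore be tested against known truth.

All randomness flows from one integer seed; per-animal substreams are
derived from ``numpy.random.SeedSequence([seed, group, animal, stage])``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .repol import QTC_RR_REF_MS, QTC_SLOPE_RABBIT

LABEL_NORMAL = "normal"
LABEL_ECTOPIC = "ectopic"
LABEL_TDP = "tdp"
BEAT_LABELS = (LABEL_NORMAL, LABEL_ECTOPIC, LABEL_TDP)

PHASE_BASELINE = "baseline"
PHASE_METHOXAMINE = "methoxamine"
PHASE_DOFETILIDE_LOW = "dofetilide_low"
PHASE_DOFETILIDE_HIGH = "dofetilide_high"
DEFAULT_PHASES = (
    (PHASE_BASELINE, 600.0),
    (PHASE_METHOXAMINE, 600.0),
    (PHASE_DOFETILIDE_LOW, 1200.0),
    (PHASE_DOFETILIDE_HIGH, 1200.0),
)


def substream(seed: int, *keys: int) -> np.random.Generator:
    """Named random substream: one seed, hashed with integer stage keys."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), *[int(k) for k in keys]]))


@dataclass(frozen=True)
class PhaseProtocol:
    """Ordered experimental phases with durations in seconds."""

    phases: tuple[tuple[str, float], ...] = DEFAULT_PHASES

    def __post_init__(self):
        labels = [p[0] for p in self.phases]
        if len(labels) != len(set(labels)):
            raise ValueError("phase labels must be unique")
        for label, dur in self.phases:
            if dur <= 0:
                raise ValueError(f"phase {label!r} has non-positive duration")

    @classmethod
    def default(cls) -> "PhaseProtocol":
        return cls()

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(p[0] for p in self.phases)

    @property
    def total_s(self) -> float:
        return float(sum(d for _, d in self.phases))

    def boundaries(self) -> list[tuple[str, float, float]]:
        """(label, start_s, end_s) per phase."""
        out, t = [], 0.0
        for label, dur in self.phases:
            out.append((label, t, t + dur))
            t += dur
        return out

    def end_of(self, label: str) -> float:
        for lab, _, end in self.boundaries():
            if lab == label:
                return end
        raise KeyError(label)


def _phase_value(value, phase: str) -> float:
    """A per-phase field may be a scalar or a mapping phase->value."""
    if isinstance(value, Mapping):
        return float(value[phase])
    return float(value)


@dataclass(frozen=True)
class GroupProfile:
    """Statistical shape of one experimental group.

    ``rr_mean_ms``/``rr_sd_ms``/``qt_mean_ms``/``qt_sd_ms`` map phase label
    to milliseconds (scalars broadcast to all phases).  ``qtc_jitter_ms`` is
    the per-beat SD of the independent QTc jitter (drives STV);  ``rr_mod``
    lists (frequency Hz, amplitude ms) sinusoidal RR modulations emulating
    LF/HF heart-rate variability; ``seb_rate``/``meb_rate`` are expected
    ectopy events per minute per phase; ``tdp_propensity`` is the
    probability of being a TdP responder under the high-dose phase.
    """

    name: str
    rr_mean_ms: Mapping[str, float] | float
    rr_sd_ms: Mapping[str, float] | float = 0.0
    qt_mean_ms: Mapping[str, float] | float = 0.0
    qt_sd_ms: Mapping[str, float] | float = 0.0
    qtc_jitter_ms: float = 0.0
    rr_mod: tuple[tuple[float, float], ...] = ()
    seb_rate: Mapping[str, float] | float = 0.0
    meb_rate: Mapping[str, float] | float = 0.0
    bigeminy: bool = False
    tdp_propensity: float = 0.0

    def validate(self, protocol: PhaseProtocol) -> None:
        for phase in protocol.labels:
            rr = _phase_value(self.rr_mean_ms, phase)
            qt = _phase_value(self.qt_mean_ms, phase)
            if rr <= 0 or qt <= 0:
                raise ValueError(
                    f"profile {self.name!r}: non-positive mean in phase {phase!r}")
            if qt >= rr:
                raise ValueError(
                    f"profile {self.name!r}: qt_mean >= rr_mean in phase {phase!r}")
            if (_phase_value(self.rr_sd_ms, phase) < 0
                    or _phase_value(self.qt_sd_ms, phase) < 0):
                raise ValueError(
                    f"profile {self.name!r}: negative SD in phase {phase!r}")
            if (_phase_value(self.seb_rate, phase) < 0
                    or _phase_value(self.meb_rate, phase) < 0):
                raise ValueError(
                    f"profile {self.name!r}: negative event rate in phase {phase!r}")
        if not 0.0 <= self.tdp_propensity <= 1.0:
            raise ValueError("tdp_propensity must lie in [0, 1]")
        for f, _a in self.rr_mod:
            if f <= 0:
                raise ValueError("modulation frequencies must be positive")


def default_profiles() -> tuple[GroupProfile, GroupProfile, GroupProfile]:
    """YC / AC / CH profiles shaped like the reported group statistics.

    Phase means and SDs follow the published group table (baseline,
    methoxamine, high-dose I_Kr block); the low-dose phase, for which only
    the high-dose recordings were reported, interpolates midway.  Baseline
    QTc jitter is set so that the implied STV (0.798 * jitter SD for
    Gaussian jitter) matches the reported baseline STV.  TdP propensities
    are the reported inducibilities (0.83 / 0.18 / 0.21).
    """
    mod = ((0.10, 8.0), (0.30, 6.0))
    yc = GroupProfile(
        name="YC",
        rr_mean_ms={"baseline": 381, "methoxamine": 502,
                    "dofetilide_low": 540, "dofetilide_high": 579},
        rr_sd_ms={"baseline": 66, "methoxamine": 81,
                  "dofetilide_low": 86, "dofetilide_high": 91},
        qt_mean_ms={"baseline": 220, "methoxamine": 250,
                    "dofetilide_low": 281, "dofetilide_high": 312},
        qt_sd_ms={"baseline": 26, "methoxamine": 24,
                  "dofetilide_low": 22, "dofetilide_high": 19},
        qtc_jitter_ms=6.8, rr_mod=mod,
        seb_rate={"baseline": 0.0, "methoxamine": 0.0,
                  "dofetilide_low": 0.3, "dofetilide_high": 1.0},
        meb_rate={"baseline": 0.0, "methoxamine": 0.0,
                  "dofetilide_low": 0.1, "dofetilide_high": 0.4},
        bigeminy=True, tdp_propensity=0.83)
    ac = GroupProfile(
        name="AC",
        rr_mean_ms={"baseline": 404, "methoxamine": 549,
                    "dofetilide_low": 540, "dofetilide_high": 532},
        rr_sd_ms={"baseline": 69, "methoxamine": 88,
                  "dofetilide_low": 78, "dofetilide_high": 67},
        qt_mean_ms={"baseline": 225, "methoxamine": 250,
                    "dofetilide_low": 287, "dofetilide_high": 324},
        qt_sd_ms={"baseline": 26, "methoxamine": 31,
                  "dofetilide_low": 38, "dofetilide_high": 46},
        qtc_jitter_ms=6.4, rr_mod=mod,
        seb_rate={"baseline": 0.0, "methoxamine": 0.0,
                  "dofetilide_low": 0.005, "dofetilide_high": 0.025},
        meb_rate={"baseline": 0.0, "methoxamine": 0.0,
                  "dofetilide_low": 0.003, "dofetilide_high": 0.012},
        bigeminy=False, tdp_propensity=0.18)
    ch = GroupProfile(
        name="CH",
        rr_mean_ms={"baseline": 376, "methoxamine": 443,
                    "dofetilide_low": 518, "dofetilide_high": 593},
        rr_sd_ms={"baseline": 57, "methoxamine": 83,
                  "dofetilide_low": 94, "dofetilide_high": 104},
        qt_mean_ms={"baseline": 205, "methoxamine": 228,
                    "dofetilide_low": 263, "dofetilide_high": 297},
        qt_sd_ms={"baseline": 21, "methoxamine": 43,
                  "dofetilide_low": 37, "dofetilide_high": 30},
        qtc_jitter_ms=7.3, rr_mod=mod,
        seb_rate={"baseline": 0.0, "methoxamine": 0.0,
                  "dofetilide_low": 0.002, "dofetilide_high": 0.01},
        meb_rate={"baseline": 0.0, "methoxamine": 0.0,
                  "dofetilide_low": 0.001, "dofetilide_high": 0.004},
        bigeminy=False, tdp_propensity=0.21)
    return yc, ac, ch


@dataclass
class BeatSeries:
    """Per-beat record: times (s), RR and QT (ms), label, phase.

    ``rr_ms[n] == (beat_time_s[n] - beat_time_s[n-1]) * 1000`` for n >= 1;
    ``rr_ms[0]`` is the interval from the record start.  QT is NaN for TdP
    beats (polymorphic complexes have no measurable QT).
    """

    beat_time_s: np.ndarray
    rr_ms: np.ndarray
    qt_ms: np.ndarray
    label: np.ndarray
    phase: np.ndarray

    def __post_init__(self):
        self.beat_time_s = np.asarray(self.beat_time_s, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        self.qt_ms = np.asarray(self.qt_ms, dtype=float)
        self.label = np.asarray(self.label, dtype=object)
        self.phase = np.asarray(self.phase, dtype=object)
        n = self.beat_time_s.size
        for name in ("rr_ms", "qt_ms", "label", "phase"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length mismatch")
        self.validate()

    def validate(self) -> None:
        t = self.beat_time_s
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if t.size > 1:
            dt_ms = np.diff(t) * 1000.0
            if not np.allclose(self.rr_ms[1:], dt_ms, rtol=0, atol=1e-6):
                raise ValueError("rr_ms inconsistent with beat times")
        bad = set(self.label) - set(BEAT_LABELS)
        if bad:
            raise ValueError(f"unknown beat labels: {sorted(bad)}")
        normal = self.label == LABEL_NORMAL
        qt = self.qt_ms[normal]
        rr = self.rr_ms[normal]
        ok = np.isnan(qt) | (qt < rr)
        if not np.all(ok):
            raise ValueError("qt_ms must be < rr_ms for normal beats")

    @property
    def n_beats(self) -> int:
        return int(self.beat_time_s.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.beat_time_s, "rr_ms": self.rr_ms,
            "qt_ms": self.qt_ms, "label": self.label, "phase": self.phase})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BeatSeries":
        return cls(frame["time_s"].to_numpy(), frame["rr_ms"].to_numpy(),
                   frame["qt_ms"].to_numpy(), frame["label"].to_numpy(),
                   frame["phase"].to_numpy())

    def slice_time(self, t0: float, t1: float) -> "BeatSeries":
        """Sub-series with beat times in [t0, t1)."""
        m = (self.beat_time_s >= t0) & (self.beat_time_s < t1)
        return BeatSeries(self.beat_time_s[m], self.rr_ms[m],
                          self.qt_ms[m], self.label[m], self.phase[m])

    def phase_mask(self, phase: str) -> np.ndarray:
        return self.phase == phase


@dataclass(frozen=True)
class TruthEvent:
    """Ground-truth injected event (SEB/MEB/bigeminy/TdP)."""

    kind: str
    start_index: int
    n_beats: int
    start_time_s: float
    end_time_s: float


def refresh_event_times(events: Sequence["TruthEvent"],
                        series: "BeatSeries") -> list["TruthEvent"]:
    """Recompute event times from beat indices after the timeline shifted
    (e.g. ectopy truth after a later TdP injection rebuilt beat times).
    Bigeminy ectopics sit at every other beat, so its end index strides 2."""
    t = series.beat_time_s
    out = []
    for e in events:
        stride = 2 if e.kind == "bigeminy" else 1
        last = e.start_index + stride * (e.n_beats - 1)
        out.append(replace(e, start_time_s=float(t[e.start_index]),
                           end_time_s=float(t[last])))
    return out


@dataclass
class EcgWaveform:
    """Sampled single-lead ECG (mV) plus optional ground-truth fiducials.

    ``fiducials`` is a DataFrame with one row per beat and float sample
    indices in columns ``p, q, r, s, t_end`` (NaN where a wave is absent,
    e.g. TdP complexes) plus the beat ``label``.
    """

    fs_hz: float
    samples: np.ndarray
    fiducials: pd.DataFrame | None = None

    def __post_init__(self):
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fiducials is not None:
            self._validate_fiducials()

    def _validate_fiducials(self) -> None:
        cols = ["p", "q", "r", "s", "t_end"]
        f = self.fiducials
        vals = f[cols].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() >= self.samples.size):
            raise ValueError("fiducial index outside sample range")
        flat = []
        for row in vals:
            flat.extend(v for v in row if np.isfinite(v))
        if np.any(np.diff(flat) <= 0):
            raise ValueError("fiducials must increase within and across beats")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz

    def time_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs_hz


# ---------------------------------------------------------------------------
# beat-series generation

def make_beat_series(profile: GroupProfile,
                     protocol: PhaseProtocol | None = None,
                     seed: int = 0,
                     rng: np.random.Generator | None = None) -> BeatSeries:
    """Generate a piecewise-stationary beat series for one animal.

    Per phase, RR is drawn i.i.d. Gaussian around the phase mean plus the
    configured sinusoidal modulations; QT follows the inverse rabbit QTc
    coupling ``QT = QTc_target + 0.175*(RR - 300)`` with QTc_target chosen
    so the phase-mean QT matches the profile, plus independent Gaussian
    jitter of SD ``qtc_jitter_ms``.  Generated QTc is therefore stationary
    by construction and STV is controlled by the jitter alone.
    """
    protocol = protocol or PhaseProtocol.default()
    profile.validate(protocol)
    rng = rng if rng is not None else substream(seed, 0)

    times, rrs, qts, phases = [], [], [], []
    t = 0.0
    for phase, _start, end in protocol.boundaries():
        rr_mu = _phase_value(profile.rr_mean_ms, phase)
        rr_sd = _phase_value(profile.rr_sd_ms, phase)
        qt_mu = _phase_value(profile.qt_mean_ms, phase)
        qtc_target = qt_mu - QTC_SLOPE_RABBIT * (rr_mu - QTC_RR_REF_MS)
        while True:
            rr = rr_mu + (rr_sd * rng.standard_normal() if rr_sd > 0 else 0.0)
            for f_hz, amp_ms in profile.rr_mod:
                rr += amp_ms * math.sin(2.0 * math.pi * f_hz * t)
            rr = max(rr, 120.0)
            t_new = t + rr / 1000.0
            if t_new >= end:
                break
            qtc = qtc_target
            if profile.qtc_jitter_ms > 0:
                qtc += profile.qtc_jitter_ms * rng.standard_normal()
            qt = qtc + QTC_SLOPE_RABBIT * (rr - QTC_RR_REF_MS)
            qt = min(max(qt, 30.0), rr - 30.0)
            times.append(t_new)
            rrs.append(rr)
            qts.append(qt)
            phases.append(phase)
            t = t_new
    return BeatSeries(np.array(times), np.array(rrs), np.array(qts),
                      np.array([LABEL_NORMAL] * len(times), dtype=object),
                      np.array(phases, dtype=object))


def _rebuild_times(rr_ms: np.ndarray) -> np.ndarray:
    return np.cumsum(rr_ms) / 1000.0


def _place_runs(rng: np.random.Generator, free: np.ndarray,
                candidates: np.ndarray, lengths: Sequence[int],
                buffer: int = 1) -> list[int]:
    """Pick non-overlapping start indices (with buffer) for runs; mark used."""
    starts = []
    order = rng.permutation(candidates)
    for length in lengths:
        placed = False
        for s in order:
            lo, hi = s - buffer, s + length + buffer
            if lo < 0 or hi > free.size:
                continue
            if np.all(free[lo:hi]):
                free[lo:hi] = False
                starts.append(int(s))
                placed = True
                break
        if not placed:
            raise ValueError(
                "requested ectopy/TdP events do not fit in the series "
                "(overlapping runs beyond series length)")
    return starts


def inject_ectopy(series: BeatSeries,
                  seb_rate: Mapping[str, float] | float = 0.0,
                  meb_rate: Mapping[str, float] | float = 0.0,
                  bigeminy: bool = False,
                  seed: int = 0,
                  rng: np.random.Generator | None = None,
                  ) -> tuple[BeatSeries, list[TruthEvent]]:
    """Inject single (SEB) and multiple (MEB, runs of 2-4) ectopic beats.

    Event counts per phase are Poisson with the given per-minute rates.
    Ectopic beats are premature: their RR is set to 0.6x the phase-mean RR
    (the beat after a run gets a 1.4x compensatory pause), guaranteeing
    >25% deviation from the segment mean so the 20% cleaning rule always
    fires.  With ``bigeminy`` one alternating normal-ectopic stretch is
    added per phase that has a non-zero rate.  Returns the modified series
    and the ground-truth event list.
    """
    for r in (seb_rate, meb_rate):
        vals = r.values() if isinstance(r, Mapping) else [r]
        if any(v < 0 for v in vals):
            raise ValueError("event rates must be >= 0")
    rng = rng if rng is not None else substream(seed, 1)

    rr = series.rr_ms.copy()
    qt = series.qt_ms.copy()
    labels = series.label.copy()
    n = series.n_beats
    free = labels == LABEL_NORMAL
    # keep one clear beat around pre-existing non-normal runs
    for i in np.flatnonzero(~(labels == LABEL_NORMAL)):
        free[max(i - 1, 0):min(i + 2, n)] = False

    truth_idx: list[tuple[str, int, int, int]] = []  # kind, start, n, last
    for phase, *_ in _phase_runs(series):
        idx = np.flatnonzero((series.phase == phase) & free)
        if idx.size == 0:
            continue
        t_phase = series.beat_time_s[series.phase == phase]
        dur_min = max(t_phase[-1] - t_phase[0], 0.0) / 60.0
        rr_mean = float(np.mean(series.rr_ms[series.phase == phase]))
        seb = _phase_value(seb_rate, phase)
        meb = _phase_value(meb_rate, phase)
        n_meb = rng.poisson(meb * dur_min) if meb > 0 else 0
        n_seb = rng.poisson(seb * dur_min) if seb > 0 else 0
        plan = [("MEB", int(rng.integers(2, 5))) for _ in range(n_meb)]
        plan += [("SEB", 1) for _ in range(n_seb)]
        if bigeminy and (seb > 0 or meb > 0):
            plan.append(("bigeminy", 2 * int(rng.integers(3, 6)) - 1))
        for kind, length in plan:
            # restrict candidate starts to this phase, run fully inside
            cands = idx[idx + length <= idx.max() + 1]
            starts = _place_runs(rng, free, cands, [length])
            s = starts[0]
            if kind == "bigeminy":
                ect = np.arange(s, s + length, 2)
                for e in ect:
                    rr[e] = 0.6 * rr_mean
                    if e + 1 < n:
                        rr[e + 1] = 1.4 * rr_mean
                    labels[e] = LABEL_ECTOPIC
                    qt[e] = min(qt[e], 0.9 * rr[e])
                # bigeminy truth counts ectopic beats; ends on the last one
                truth_idx.append((kind, s, ect.size, int(ect[-1])))
            else:
                for e in range(s, s + length):
                    rr[e] = 0.6 * rr_mean
                    labels[e] = LABEL_ECTOPIC
                    qt[e] = min(qt[e], 0.9 * rr[e])
                if s + length < n and labels[s + length] == LABEL_NORMAL:
                    rr[s + length] = 1.4 * rr_mean
                truth_idx.append((kind, s, length, s + length - 1))

    t = _rebuild_times(rr)
    out = BeatSeries(t, rr, qt, labels, series.phase.copy())
    events = [TruthEvent(kind, s, nb, float(t[s]), float(t[last]))
              for kind, s, nb, last in sorted(truth_idx, key=lambda e: e[1])]
    return out, events


def _phase_runs(series: BeatSeries):
    """Yield (phase, start_index, end_index) in series order."""
    seen = []
    for phase in pd.unique(series.phase):
        idx = np.flatnonzero(series.phase == phase)
        seen.append((phase, int(idx[0]), int(idx[-1])))
    return seen


def inject_tdp(series: BeatSeries, n_episodes: int,
               episode_beats: int = 9, seed: int = 0,
               rng: np.random.Generator | None = None,
               phase: str | None = None,
               ) -> tuple[BeatSeries, list[TruthEvent]]:
    """Inject TdP episodes: contiguous runs of >= 5 polymorphic beats.

    Episode beats get label ``tdp``, shortened irregular RR (0.45x the
    phase-mean RR, +/-15% uniform) and NaN QT.  Episodes are placed in the
    given phase (default: the last phase of the record).
    """
    if episode_beats < 5:
        raise ValueError("a TdP episode needs at least 5 beats")
    if n_episodes < 0:
        raise ValueError("n_episodes must be >= 0")
    if n_episodes == 0:
        return series, []
    rng = rng if rng is not None else substream(seed, 2)
    phase = phase if phase is not None else series.phase[-1]

    rr = series.rr_ms.copy()
    qt = series.qt_ms.copy()
    labels = series.label.copy()
    n = series.n_beats
    free = labels == LABEL_NORMAL
    for i in np.flatnonzero(~(labels == LABEL_NORMAL)):
        free[max(i - 1, 0):min(i + 2, n)] = False
    idx = np.flatnonzero((series.phase == phase) & free)
    if idx.size == 0:
        raise ValueError(f"no room for TdP episodes in phase {phase!r}")
    rr_mean = float(np.mean(series.rr_ms[series.phase == phase]))

    cands = idx[idx + episode_beats <= idx.max() + 1]
    starts = _place_runs(rng, free, cands, [episode_beats] * n_episodes)
    for s in starts:
        for e in range(s, s + episode_beats):
            rr[e] = 0.45 * rr_mean * (1.0 + rng.uniform(-0.15, 0.15))
            labels[e] = LABEL_TDP
            qt[e] = np.nan

    t = _rebuild_times(rr)
    out = BeatSeries(t, rr, qt, labels, series.phase.copy())
    events = [TruthEvent("TdP", s, episode_beats, float(t[s]),
                         float(t[s + episode_beats - 1]))
              for s in sorted(starts)]
    return out, events


# ---------------------------------------------------------------------------
# waveform rendering

def _add_gauss(x: np.ndarray, fs: float, center_s: float, sd_s: float,
               amp: float) -> None:
    lo = max(int((center_s - 4 * sd_s) * fs), 0)
    hi = min(int((center_s + 4 * sd_s) * fs) + 1, x.size)
    if hi <= lo:
        return
    tt = np.arange(lo, hi) / fs
    x[lo:hi] += amp * np.exp(-0.5 * ((tt - center_s) / sd_s) ** 2)


def render_waveform(series: BeatSeries, fs_hz: float = 1000.0,
                    noise_sd_mv: float = 0.0, seed: int = 0,
                    rng: np.random.Generator | None = None,
                    amp_jitter_frac: float = 0.0) -> EcgWaveform:
    """Render a beat series as a PQRST waveform with ground-truth fiducials.

    Normal and ectopic beats are sums of Gaussian waves anchored to the R
    time; T placement is tied to the series QT so ``t_end - q`` reproduces
    it.  TdP beats are wide monophasic complexes with sinusoidally modulated
    amplitude and alternating polarity (the twisting morphology).
    ``amp_jitter_frac`` applies multiplicative sample-wise amplitude noise
    (subtle beat-shape irregularity); ``noise_sd_mv`` adds white noise.
    Deterministic for a fixed seed.
    """
    if fs_hz < 250:
        raise ValueError("sampling rate must be >= 250 Hz")
    rng = rng if rng is not None else substream(seed, 3)
    t = series.beat_time_s
    n_samp = int(math.ceil((t[-1] + 0.4) * fs_hz)) if t.size else int(fs_hz)
    x = np.zeros(n_samp)
    fid_rows = []

    tdp_run = 0
    for i in range(series.n_beats):
        r_t = t[i]
        label = series.label[i]
        next_rr_s = (t[i + 1] - t[i]) if i + 1 < series.n_beats else \
            series.rr_ms[i] / 1000.0
        row = {"p": np.nan, "q": np.nan, "r": np.nan, "s": np.nan,
               "t_end": np.nan, "label": label}
        if label == LABEL_TDP:
            amp = 0.50 + 0.50 * (0.5 + 0.5 * math.cos(2 * math.pi * tdp_run / 10))
            sign = 1.0 if tdp_run % 2 == 0 else -1.0
            _add_gauss(x, fs_hz, r_t, 0.016, sign * amp)
            row["r"] = float(round(r_t * fs_hz))
            tdp_run += 1
        else:
            tdp_run = 0
            qt_s = series.qt_ms[i] / 1000.0
            qt_s = min(qt_s, next_rr_s - 0.030)  # keep T end before next P
            q_on = r_t - 0.035
            t_end = q_on + qt_s
            t_sd = 0.025
            if label == LABEL_NORMAL:
                _add_gauss(x, fs_hz, r_t - 0.060, 0.012, 0.10)   # P
                _add_gauss(x, fs_hz, r_t - 0.018, 0.004, -0.10)  # Q
                _add_gauss(x, fs_hz, r_t, 0.008, 1.00)           # R
                _add_gauss(x, fs_hz, r_t + 0.018, 0.004, -0.20)  # S
                _add_gauss(x, fs_hz, t_end - 2.5 * t_sd, t_sd, 0.25)  # T
                row.update(p=round((r_t - 0.060) * fs_hz),
                           q=round(q_on * fs_hz),
                           r=round(r_t * fs_hz),
                           s=round((r_t + 0.018) * fs_hz),
                           t_end=round(t_end * fs_hz))
            else:  # ectopic: wide bizarre complex, no P, inverted T
                _add_gauss(x, fs_hz, r_t, 0.014, 1.10)
                _add_gauss(x, fs_hz, r_t + 0.026, 0.008, -0.30)
                _add_gauss(x, fs_hz, t_end - 2.5 * t_sd, t_sd, -0.20)
                row.update(q=round(q_on * fs_hz),
                           r=round(r_t * fs_hz),
                           s=round((r_t + 0.026) * fs_hz),
                           t_end=round(t_end * fs_hz))
        for k in ("p", "q", "r", "s", "t_end"):
            v = row[k]
            if np.isfinite(v) and not (0 <= v < n_samp):
                row[k] = np.nan
        fid_rows.append(row)

    if amp_jitter_frac > 0:
        x = x * (1.0 + amp_jitter_frac * rng.standard_normal(n_samp))
    if noise_sd_mv > 0:
        x = x + noise_sd_mv * rng.standard_normal(n_samp)
    fid = pd.DataFrame(fid_rows, columns=["p", "q", "r", "s", "t_end", "label"])
    return EcgWaveform(fs_hz=fs_hz, samples=x, fiducials=fid)


# ---------------------------------------------------------------------------
# cohort generation

@dataclass
class CohortAnimal:
    animal_id: str
    group: str
    series: BeatSeries
    waveform: EcgWaveform | None
    truth: dict


@dataclass
class Cohort:
    seed: int
    animals: list[CohortAnimal] = field(default_factory=list)

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "n_animals": len(self.animals),
            "animals": [
                {"id": a.animal_id, "group": a.group,
                 "n_beats": a.series.n_beats,
                 "has_waveform": a.waveform is not None}
                for a in self.animals],
        }


def responder_flags(profiles: Sequence[GroupProfile],
                    n_per_group: int | Sequence[int],
                    seed: int) -> dict[str, list[bool]]:
    """Per-animal TdP responder status, drawn from ``tdp_propensity``.

    Uses the same per-animal substreams as :func:`generate_cohort`, so the
    flags match the cohort the same seed produces.
    """
    if not profiles:
        raise ValueError("at least one group profile is required")
    ns = ([int(n_per_group)] * len(profiles)
          if isinstance(n_per_group, int) else [int(v) for v in n_per_group])
    if len(ns) != len(profiles) or any(v < 1 for v in ns):
        raise ValueError("n_per_group must be >= 1 for every profile")
    out: dict[str, list[bool]] = {}
    for gi, (profile, n) in enumerate(zip(profiles, ns)):
        flags = []
        for ai in range(n):
            r = substream(seed, gi, ai, 1).random()
            flags.append(bool(r < profile.tdp_propensity))
        out[profile.name] = flags
    return out


def generate_cohort(profiles: Sequence[GroupProfile],
                    n_per_group: int | Sequence[int],
                    seed: int,
                    protocol: PhaseProtocol | None = None,
                    render: bool = True,
                    fs_hz: float = 1000.0,
                    waveform_seconds: float = 60.0,
                    noise_sd_mv: float = 0.01,
                    responder_amp_jitter: float = 0.1,
                    episode_beats: int = 9,
                    n_episodes_responder: int = 3) -> Cohort:
    """Simulate a full cohort with ground truth for every stage.

    Each animal gets a beat series over the protocol, profile-rate ectopy,
    and (for responders, drawn with ``tdp_propensity``) TdP episodes in the
    high-dose phase.  If ``render`` is true, the first ``waveform_seconds``
    of baseline are rendered at ``fs_hz``; arrhythmia-prone animals
    (responders or animals with any injected ectopy) additionally carry the
    ``responder_amp_jitter`` multiplicative amplitude jitter, the baseline
    irregularity the entropy stage is designed to detect.
    """
    protocol = protocol or PhaseProtocol.default()
    flags = responder_flags(profiles, n_per_group, seed)
    cohort = Cohort(seed=seed)
    for gi, profile in enumerate(profiles):
        for ai, responder in enumerate(flags[profile.name]):
            series = make_beat_series(profile, protocol,
                                      rng=substream(seed, gi, ai, 2))
            series, events = inject_ectopy(
                series, profile.seb_rate, profile.meb_rate, profile.bigeminy,
                rng=substream(seed, gi, ai, 3))
            if responder:
                series, tdp_events = inject_tdp(
                    series, n_episodes_responder, episode_beats,
                    rng=substream(seed, gi, ai, 4))
                events = sorted(refresh_event_times(events, series)
                                + tdp_events, key=lambda e: e.start_index)
            prone = responder or bool(events)
            waveform = None
            if render:
                base = series.slice_time(0.0, waveform_seconds)
                waveform = render_waveform(
                    base, fs_hz=fs_hz, noise_sd_mv=noise_sd_mv,
                    rng=substream(seed, gi, ai, 5),
                    amp_jitter_frac=responder_amp_jitter if prone else 0.0)
            cohort.animals.append(CohortAnimal(
                animal_id=f"{profile.name}{ai + 1:02d}",
                group=profile.name, series=series, waveform=waveform,
                truth={"responder": responder, "prone": prone,
                       "amp_jitter": responder_amp_jitter if prone else 0.0,
                       "events": [e.__dict__ for e in events]}))
    return cohort
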