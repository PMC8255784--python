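"""Arrhythmia-event classification and outcome rules.

Episode taxonomy follows the rabbit TdP protocol: a single ectopic beat
(SEB), a run of two to four ectopic beats (MEB), an alternating
normal-ectopic rhythm of at least three alternations (bigeminy), and
torsades de pointes (TdP): at least five consecutive undulating
polymorphic complexes.  An animal is TdP-inducible when at least three
TdP episodes occurred or when one episode lasted more than 10 s (strict);
the experiment terminates once a single episode persists for 20 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beats import DetectionConfig, detect_r_peaks, rr_from_peaks
from .synth import (BEAT_LABELS, LABEL_ECTOPIC, LABEL_NORMAL, LABEL_TDP,
                    EcgWaveform, PhaseProtocol)

KIND_SEB = "SEB"
KIND_MEB = "MEB"
KIND_BIGEMINY = "bigeminy"
KIND_TDP = "TdP"

CATEGORY_NONE = "no_arrhythmia"
CATEGORY_NON_TDP = "non_tdp"
CATEGORY_TDP = "tdp"


@dataclass(frozen=True)
class Episode:
    kind: str
    start_time_s: float
    end_time_s: float
    n_beats: int
    start_index: int = -1

    def __post_init__(self):
        if self.end_time_s < self.start_time_s:
            raise ValueError("episode end must be >= start")
        if self.kind == KIND_TDP and self.n_beats < 5:
            raise ValueError("TdP episodes have >= 5 beats")
        if self.kind == KIND_MEB and not 2 <= self.n_beats <= 4:
            raise ValueError("MEB episodes have 2-4 beats")
        if self.kind == KIND_SEB and self.n_beats != 1:
            raise ValueError("SEB episodes have exactly 1 beat")

    @property
    def duration_s(self) -> float:
        return self.end_time_s - self.start_time_s


@dataclass
class AnimalOutcome:
    animal_id: str
    episodes: list[Episode]
    category: str
    inducible: bool
    seb_present: bool
    meb_present: bool
    extra: dict = field(default_factory=dict)


def _split_long_run(length: int) -> list[int]:
    """Partition an ectopic run > 4 into MEB lengths in {2, 3, 4}."""
    out: list[int] = []
    rem = length
    while rem > 4:
        if rem == 5:
            out.append(3)
            rem = 2
        else:
            out.append(4)
            rem -= 4
    out.append(rem)
    return out


def classify_runs(labels, times,
                  bigeminy_min_alternations: int = 3) -> list[Episode]:
    """Partition maximal non-normal label runs into episodes.

    Ectopic runs of length 1 become SEB candidates, 2-4 MEB; longer runs
    (not produced by the generator) are split into consecutive MEBs.
    ``tdp`` runs of >= 5 beats are TdP episodes (shorter salvos degrade to
    MEB/SEB).  SEB candidates separated by exactly one normal beat chain
    into a bigeminy episode once at least ``bigeminy_min_alternations``
    alternations occur, subsuming those singles.
    """
    labels = np.asarray(labels, dtype=object)
    times = np.asarray(times, dtype=float)
    if labels.size != times.size:
        raise ValueError("labels and times must align")
    bad = set(labels) - set(BEAT_LABELS)
    if bad:
        raise ValueError(f"unknown label value(s): {sorted(bad)}")

    episodes: list[Episode] = []
    singles: list[int] = []

    i = 0
    n = labels.size
    while i < n:
        lab = labels[i]
        j = i
        while j < n and labels[j] == lab:
            j += 1
        length = j - i
        if lab == LABEL_TDP and length >= 5:
            episodes.append(Episode(KIND_TDP, times[i], times[j - 1],
                                    length, i))
        elif lab in (LABEL_ECTOPIC, LABEL_TDP):
            if length == 1:
                singles.append(i)
            else:
                s = i
                for seg in _split_long_run(length):
                    episodes.append(Episode(KIND_MEB, times[s],
                                            times[s + seg - 1], seg, s))
                    s += seg
        i = j

    # chain singles separated by exactly one normal beat into bigeminy
    chain: list[int] = []
    for s in singles + [-10]:
        if chain and s - chain[-1] == 2:
            chain.append(s)
            continue
        if len(chain) >= bigeminy_min_alternations:
            episodes.append(Episode(KIND_BIGEMINY, times[chain[0]],
                                    times[chain[-1]], len(chain), chain[0]))
        else:
            episodes.extend(Episode(KIND_SEB, times[c], times[c], 1, c)
                            for c in chain)
        chain = [s]
    return sorted(episodes, key=lambda e: e.start_time_s)


def tdp_inducible(episodes, min_episodes: int = 3,
                  min_duration_s: float = 10.0,
                  strict_duration: bool = True) -> bool:
    """True iff >= ``min_episodes`` TdP episodes or one lasting more than
    ``min_duration_s`` (strict inequality by default)."""
    tdps = [e for e in episodes if e.kind == KIND_TDP]
    if len(tdps) >= min_episodes:
        return True
    for e in tdps:
        if (e.duration_s > min_duration_s if strict_duration
                else e.duration_s >= min_duration_s):
            return True
    return False


def termination_check(episodes, protocol: PhaseProtocol | None = None,
                      persist_s: float = 20.0,
                      strict: bool = False) -> float:
    """First time a single TdP episode reaches ``persist_s`` of persistent
    arrhythmia (non-strict by default), else the protocol end time."""
    protocol = protocol or PhaseProtocol.default()
    hits = []
    for e in episodes:
        if e.kind != KIND_TDP:
            continue
        ok = e.duration_s > persist_s if strict else e.duration_s >= persist_s
        if ok:
            hits.append(e.start_time_s + persist_s)
    return min(hits) if hits else protocol.total_s


def outcome_category(episodes, animal_id: str = "",
                     **inducible_kwargs) -> AnimalOutcome:
    """Per-animal outcome: tdp / non_tdp / no_arrhythmia.

    SEB/MEB presence flags consider only episodes starting before the
    first TdP onset (ectopy "prior to TdP arrhythmia").
    """
    episodes = sorted(episodes, key=lambda e: e.start_time_s)
    inducible = tdp_inducible(episodes, **inducible_kwargs)
    tdp_onsets = [e.start_time_s for e in episodes if e.kind == KIND_TDP]
    cutoff = min(tdp_onsets) if tdp_onsets else float("inf")
    pre = [e for e in episodes
           if e.kind != KIND_TDP and e.start_time_s < cutoff]
    if inducible:
        category = CATEGORY_TDP
    elif episodes:
        category = CATEGORY_NON_TDP
    else:
        category = CATEGORY_NONE
    return AnimalOutcome(
        animal_id=animal_id, episodes=episodes, category=category,
        inducible=inducible,
        seb_present=any(e.kind == KIND_SEB for e in pre),
        meb_present=any(e.kind == KIND_MEB for e in pre))


def incidence(outcomes, predicate) -> tuple[int, int, int]:
    """(k, n, percent) of outcomes satisfying ``predicate``; the percent is
    rounded half-up to integer."""
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("empty cohort")
    k = sum(1 for o in outcomes if predicate(o))
    return incidence_from_counts(k, len(outcomes))


def incidence_from_counts(k: int, n: int) -> tuple[int, int, int]:
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    percent = int(np.floor(100.0 * k / n + 0.5))
    return k, n, percent


def labels_from_waveform(waveform: EcgWaveform,
                         config: DetectionConfig | None = None,
                         ectopic_frac: float = 0.20,
                         tdp_rr_frac: float = 0.6,
                         tdp_min_run: int = 5,
                         tdp_alternation_frac: float = 0.5,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Infer beat labels from a raw waveform (waveform mode).

    Beats are detected with the derivative-threshold algorithm.  TdP is
    operationalized as a run of >= ``tdp_min_run`` complexes whose RR is
    below ``tdp_rr_frac`` of the record-mean RR and whose R-peak polarity
    alternates across the run envelope.  Remaining premature beats (RR
    shorter than the mean by more than ``ectopic_frac``) are labelled
    ectopic; compensatory pauses stay normal.  Returns (times, labels).
    """
    if config is None:
        # polymorphic TdP complexes are shallower than normal R upstrokes,
        # so arrhythmia screening needs a more permissive crossing threshold
        config = DetectionConfig(derivative_threshold_frac=0.2)
    times = detect_r_peaks(waveform, config)
    if times.size < 3:
        return times, np.array([LABEL_NORMAL] * times.size, dtype=object)
    rr = rr_from_peaks(times)
    amp = waveform.samples[np.round(times * waveform.fs_hz).astype(int).clip(
        0, waveform.samples.size - 1)]
    mean_rr = float(rr.mean())
    labels = np.array([LABEL_NORMAL] * times.size, dtype=object)
    short = np.concatenate([[False], rr < tdp_rr_frac * mean_rr])
    # TdP: long short-RR runs with alternating polarity
    i = 0
    n = times.size
    while i < n:
        if not short[i]:
            i += 1
            continue
        j = i
        while j < n and short[j]:
            j += 1
        run = np.arange(i - 1, j)  # include the beat opening the run
        if run.size >= tdp_min_run:
            signs = np.sign(amp[run])
            flips = np.count_nonzero(signs[:-1] * signs[1:] < 0)
            if flips >= tdp_alternation_frac * (run.size - 1):
                labels[run] = LABEL_TDP
        i = j
    # ectopic: premature beats not already part of a TdP run
    for b in range(1, n):
        if labels[b] != LABEL_NORMAL:
            continue
        if (mean_rr - rr[b - 1]) / mean_rr > ectopic_frac:
            labels[b] = LABEL_ECTOPIC
    return times, labels
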