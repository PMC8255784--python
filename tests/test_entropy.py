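"""Ordinal patterns, AAPE, rePE and the IEIN temporal-irregularity index."""

import itertools
import math

import numpy as np
import pytest

import rabbitecg as r
from rabbitecg.entropy import (IeinConfig, OrdinalConfig, SegmentTooShort,
                               iein_sigma, windowed_repe_trace)


def aape_bruteforce(x, m, tau, A):
    """Independent oracle: explicit loop over embedded vectors."""
    x = np.asarray(x, dtype=float)
    weights = {}
    n = len(x) - (m - 1) * tau
    for i in range(n):
        v = x[i:i + (m - 1) * tau + 1:tau]
        perm = tuple(np.argsort(v, kind="stable"))
        w = (A / m) * np.sum(np.abs(v))
        if m > 1:
            w += ((1 - A) / (m - 1)) * np.sum(np.abs(np.diff(v)))
        weights[perm] = weights.get(perm, 0.0) + w
    total = sum(weights.values())
    if total == 0:
        return 0.0
    h = 0.0
    for w in weights.values():
        p = w / total
        if p > 0:
            h -= p * math.log(p)
    return h


class TestOrdinalPattern:
    def test_ascending_and_descending(self):
        assert r.ordinal_pattern([1.0, 2.0]) == 0
        assert r.ordinal_pattern([2.0, 1.0]) == 1

    def test_all_orderings_enumerate_all_patterns(self):
        codes = {r.ordinal_pattern(list(p))
                 for p in itertools.permutations([10.0, 20.0, 30.0])}
        assert codes == set(range(6))

    def test_ties_rank_earlier_sample_lower(self):
        # (5, 5) ties: earlier index ranks lower -> ascending pattern
        assert r.ordinal_pattern([5.0, 5.0]) == r.ordinal_pattern([1.0, 2.0])

    def test_bijective_for_m4(self):
        codes = {r.ordinal_pattern(list(p))
                 for p in itertools.permutations([1.0, 2.0, 3.0, 4.0])}
        assert codes == set(range(24))


class TestAape:
    def test_hand_computed_example(self):
        """(4,1,3,2,5), m=2, A=0.5: weights 5.25/4.5 of 9.75."""
        cfg = OrdinalConfig(m=2, tau=1, adjustment=0.5)
        value, p = r.aape([4, 1, 3, 2, 5], cfg, return_distribution=True)
        assert sorted(p[p > 0]) == pytest.approx([4.5 / 9.75, 5.25 / 9.75])
        assert value == pytest.approx(0.6902, abs=1e-4)

    def test_monotone_series_is_zero(self):
        assert r.aape(np.arange(50, dtype=float), OrdinalConfig(m=3)) == 0.0

    def test_scale_invariance(self):
        x = np.random.default_rng(0).normal(size=300)
        assert r.aape(17.3 * x) == pytest.approx(r.aape(x), abs=1e-12)

    def test_weight_normalization(self):
        for seed in range(5):
            x = np.random.default_rng(seed).normal(size=200)
            _, p = r.aape(x, return_distribution=True)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_bounded_by_log_m_factorial(self):
        for m in (2, 3, 4):
            x = np.random.default_rng(m).normal(size=2000)
            assert 0.0 <= r.aape(x, OrdinalConfig(m=m)) <= math.log(
                math.factorial(m)) + 1e-12

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            m = int(rng.integers(2, 5))
            n = int(rng.integers(m + 2, 30))
            x = rng.normal(size=n)
            got = r.aape(x, OrdinalConfig(m=m))
            assert got == pytest.approx(aape_bruteforce(x, m, 1, 0.5),
                                        abs=1e-12)

    def test_all_zero_series_is_zero(self):
        assert r.aape(np.zeros(50)) == 0.0

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            r.aape([1.0, 2.0], OrdinalConfig(m=4))

    def test_not_invariant_under_monotone_transform(self):
        x = np.random.default_rng(1).normal(size=400)
        assert abs(r.aape(np.exp(x)) - r.aape(x)) > 1e-3


class TestRepe:
    def test_monotone_series_is_zero(self):
        assert r.repe(np.arange(20, dtype=float)) == 0.0

    def test_equals_aape_for_alternating_series(self):
        """Alternating +/-c: every vector has identical amplitude weight."""
        x = np.array([3.0, -3.0] * 30)
        cfg = OrdinalConfig(m=2)
        assert r.repe(x, cfg) == pytest.approx(r.aape(x, cfg), abs=1e-12)

    def test_uniform_pattern_limit(self):
        """i.i.d. continuous noise approaches log(m!) for long series."""
        x = np.random.default_rng(7).random(100_000)
        h = r.repe(x, OrdinalConfig(m=3))
        assert h == pytest.approx(math.log(6), rel=0.02)

    def test_invariant_under_monotone_transform(self):
        x = np.random.default_rng(2).normal(size=400)
        assert r.repe(np.exp(x)) == pytest.approx(r.repe(x), abs=1e-12)


class TestIeinSigma:
    CFG = IeinConfig(window=200, hop=100, windows_per_block=8)

    @staticmethod
    def _step_record(rng, n):
        x = rng.normal(size=n)
        # smooth the second half: windowed entropy steps down mid-record
        x[n // 2:] = np.convolve(x[n // 2:], np.ones(5) / 5, mode="same")
        return x

    def test_nonstationary_exceeds_stationary_calibration(self):
        """Step-change records beat the stationary 95th percentile."""
        stat, step = [], []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            stat.append(iein_sigma(rng.normal(size=20_000), self.CFG))
            rng2 = np.random.default_rng(1000 + seed)
            step.append(iein_sigma(self._step_record(rng2, 20_000), self.CFG))
        q95 = np.quantile(stat, 0.95)
        assert np.mean(np.asarray(step) > q95) >= 0.9

    def test_deterministic_on_duplicate_record(self):
        x = np.random.default_rng(3).normal(size=20_000)
        assert iein_sigma(x, self.CFG) == iein_sigma(x.copy(), self.CFG)

    def test_too_short_record_rejected(self):
        with pytest.raises(ValueError, match="two IEIN blocks"):
            iein_sigma(np.random.default_rng(0).normal(size=1000), self.CFG)

    def test_trace_length(self):
        x = np.zeros(1000)
        trace = windowed_repe_trace(x, IeinConfig(window=200, hop=100))
        assert trace.size == 9


class TestEntropyForAnimal:
    def test_amplitude_jitter_raises_aape_paired(self, yc_profile):
        """Jittered baseline waveforms score strictly higher AAPE than the
        same animal rendered without jitter, across 30 paired seeds."""
        proto = r.PhaseProtocol((("baseline", 25.0),))
        wins = 0
        n_pairs = 30
        for seed in range(n_pairs):
            s = r.make_beat_series(yc_profile, proto, seed=seed)
            plain = r.render_waveform(s, fs_hz=500, noise_sd_mv=0.0,
                                      seed=seed, amp_jitter_frac=0.0)
            jit = r.render_waveform(s, fs_hz=500, noise_sd_mv=0.0,
                                    seed=seed, amp_jitter_frac=0.1)
            a0 = r.entropy_for_animal(plain, min_seconds=20.0).aape
            a1 = r.entropy_for_animal(jit, min_seconds=20.0).aape
            wins += a1 > a0
        assert wins == n_pairs

    def test_deterministic(self, yc_profile):
        s = r.make_beat_series(
            yc_profile, r.PhaseProtocol((("baseline", 25.0),)), seed=1)
        wf = r.render_waveform(s, fs_hz=500, noise_sd_mv=0.01, seed=1)
        r1 = r.entropy_for_animal(wf)
        r2 = r.entropy_for_animal(wf)
        assert r1.aape == r2.aape and r1.iein_sigma == r2.iein_sigma

    def test_short_segment_excluded_with_reason(self, yc_profile):
        s = r.make_beat_series(
            yc_profile, r.PhaseProtocol((("baseline", 6.0),)), seed=1)
        wf = r.render_waveform(s, fs_hz=500, seed=1)
        with pytest.raises(SegmentTooShort, match="shorter"):
            r.entropy_for_animal(wf, min_seconds=20.0)

    def test_segment_bounds_recorded(self, yc_profile):
        s = r.make_beat_series(
            yc_profile, r.PhaseProtocol((("baseline", 30.0),)), seed=2)
        wf = r.render_waveform(s, fs_hz=500, seed=2)
        res = r.entropy_for_animal(wf, segment_s=(0.0, 25.0))
        assert res.segment_s == (0.0, 25.0)
        assert res.config["ordinal"]["m"] == 4
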