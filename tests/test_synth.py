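"""Generator contracts: interval statistics, event injection, rendering."""

import numpy as np
import pytest

import rabbitecg as r
from rabbitecg.synth import LABEL_ECTOPIC, LABEL_NORMAL, LABEL_TDP


class TestMakeBeatSeries:
    def test_zero_variance_series_is_constant(self, flat_profile):
        proto = r.PhaseProtocol((("baseline", 60.0), ("methoxamine", 60.0),
                                 ("dofetilide_low", 60.0),
                                 ("dofetilide_high", 60.0)))
        s = r.make_beat_series(flat_profile, proto, seed=0)
        assert np.allclose(s.rr_ms, 400.0)
        assert np.allclose(s.qt_ms, 200.0)

    def test_phase_means_track_profile(self, yc_baseline_series, yc_profile):
        """YC baseline sample means stay within 3 SE of the group targets."""
        s = yc_baseline_series
        n = s.n_beats
        se_rr = s.rr_ms.std(ddof=1) / np.sqrt(n)
        se_qt = s.qt_ms.std(ddof=1) / np.sqrt(n)
        assert abs(s.rr_ms.mean() - 381) < 3 * se_rr + 1.0
        assert abs(s.qt_ms.mean() - 220) < 3 * se_qt + 1.0

    @pytest.mark.parametrize("seed", range(0, 100, 1))
    def test_monotone_times_and_rr_consistency(self, yc_profile, seed):
        s = r.make_beat_series(
            yc_profile, r.PhaseProtocol((("baseline", 60.0),)), seed=seed)
        assert np.all(np.diff(s.beat_time_s) > 0)
        assert np.allclose(s.rr_ms[1:], np.diff(s.beat_time_s) * 1000.0,
                           atol=1e-6)

    def test_invalid_profile_names_phase(self):
        bad = r.GroupProfile(name="bad", rr_mean_ms=300.0, qt_mean_ms=350.0)
        with pytest.raises(ValueError, match="baseline"):
            r.make_beat_series(bad, r.PhaseProtocol((("baseline", 10.0),)))

    def test_deterministic_for_fixed_seed(self, yc_profile):
        proto = r.PhaseProtocol((("baseline", 30.0),))
        a = r.make_beat_series(yc_profile, proto, seed=5)
        b = r.make_beat_series(yc_profile, proto, seed=5)
        assert np.array_equal(a.rr_ms, b.rr_ms)
        assert np.array_equal(a.qt_ms, b.qt_ms)


class TestInjectEctopy:
    def test_zero_rates_identity(self, yc_baseline_series):
        out, events = r.inject_ectopy(yc_baseline_series, 0.0, 0.0,
                                      bigeminy=False, seed=1)
        assert events == []
        assert np.array_equal(out.rr_ms, yc_baseline_series.rr_ms)
        assert np.array_equal(out.label, yc_baseline_series.label)

    def test_meb_runs_have_length_2_to_4(self, yc_baseline_series):
        out, events = r.inject_ectopy(yc_baseline_series, 0.0, 3.0,
                                      bigeminy=False, seed=2)
        mebs = [e for e in events if e.kind == "MEB"]
        assert mebs and all(2 <= e.n_beats <= 4 for e in mebs)

    def test_seb_counts_are_poisson(self, flat_profile):
        """2 SEB/min over 10 min: mean inserted count about 20."""
        proto = r.PhaseProtocol((("baseline", 600.0),))
        base = r.make_beat_series(flat_profile, proto, seed=0)
        counts = [len(r.inject_ectopy(base, 2.0, 0.0, False, seed=s)[1])
                  for s in range(100)]
        mean = np.mean(counts)
        # SE of the mean of 100 Poisson(20) draws is sqrt(20/100) ~ 0.45
        assert abs(mean - 20.0) < 3 * np.sqrt(20.0 / 100.0) + 0.2

    def test_truth_matches_label_runs(self, yc_baseline_series):
        out, events = r.inject_ectopy(yc_baseline_series, 2.0, 1.0,
                                      bigeminy=True, seed=3)
        for e in events:
            if e.kind == "SEB":
                i = e.start_index
                assert out.label[i] == LABEL_ECTOPIC
                assert out.label[i - 1] == LABEL_NORMAL
                assert out.label[i + 1] == LABEL_NORMAL
            elif e.kind == "MEB":
                run = out.label[e.start_index:e.start_index + e.n_beats]
                assert all(run == LABEL_ECTOPIC)
            elif e.kind == "bigeminy":
                idx = e.start_index + 2 * np.arange(e.n_beats)
                assert all(out.label[idx] == LABEL_ECTOPIC)

    def test_ectopic_rr_deviation_exceeds_quarter(self, yc_baseline_series):
        out, events = r.inject_ectopy(yc_baseline_series, 2.0, 1.0,
                                      bigeminy=False, seed=4)
        mean_rr = yc_baseline_series.rr_ms.mean()
        ect = out.rr_ms[out.label == LABEL_ECTOPIC]
        assert np.all(np.abs(ect - mean_rr) / mean_rr > 0.25)

    def test_overfull_request_rejected(self, flat_profile):
        proto = r.PhaseProtocol((("baseline", 12.0),))
        base = r.make_beat_series(flat_profile, proto, seed=0)
        with pytest.raises(ValueError, match="do not fit"):
            r.inject_ectopy(base, 0.0, 600.0, False, seed=0)

    def test_negative_rate_rejected(self, yc_baseline_series):
        with pytest.raises(ValueError, match=">= 0"):
            r.inject_ectopy(yc_baseline_series, -1.0, 0.0, False, seed=0)


class TestInjectTdp:
    def test_zero_episodes_identity(self, yc_baseline_series):
        out, events = r.inject_tdp(yc_baseline_series, 0, seed=0)
        assert events == [] and out is yc_baseline_series

    def test_short_episode_rejected(self, yc_baseline_series):
        with pytest.raises(ValueError, match="at least 5"):
            r.inject_tdp(yc_baseline_series, 1, episode_beats=4, seed=0)

    def test_three_episodes_make_animal_inducible(self, yc_baseline_series):
        out, _ = r.inject_tdp(yc_baseline_series, 3, episode_beats=8, seed=1)
        eps = r.classify_runs(out.label, out.beat_time_s)
        assert r.tdp_inducible(eps)

    def test_long_episode_alone_is_inducible(self, yc_baseline_series):
        # ~60 beats of 0.45x mean RR span well over 10 s
        out, events = r.inject_tdp(yc_baseline_series, 1, episode_beats=60,
                                   seed=2)
        assert events[0].end_time_s - events[0].start_time_s > 10.0
        eps = r.classify_runs(out.label, out.beat_time_s)
        assert r.tdp_inducible(eps)


class TestRenderWaveform:
    def test_bit_identical_for_fixed_seed(self, yc_profile):
        s = r.make_beat_series(
            yc_profile, r.PhaseProtocol((("baseline", 20.0),)), seed=3)
        a = r.render_waveform(s, fs_hz=500, noise_sd_mv=0.02, seed=9)
        b = r.render_waveform(s, fs_hz=500, noise_sd_mv=0.02, seed=9)
        assert np.array_equal(a.samples, b.samples)

    def test_noiseless_r_fiducials_are_local_maxima(self, yc_profile):
        s = r.make_beat_series(
            yc_profile, r.PhaseProtocol((("baseline", 30.0),)), seed=4)
        wf = r.render_waveform(s, fs_hz=1000, noise_sd_mv=0.0, seed=0)
        x = wf.samples
        for idx in wf.fiducials["r"].dropna().astype(int):
            assert x[idx] >= x[idx - 1] and x[idx] >= x[idx + 1]

    def test_tdp_polarity_alternates(self, flat_profile):
        proto = r.PhaseProtocol((("baseline", 120.0),))
        s = r.make_beat_series(flat_profile, proto, seed=0)
        s2, events = r.inject_tdp(s, 1, episode_beats=10, seed=1)
        wf = r.render_waveform(s2, fs_hz=500, noise_sd_mv=0.0, seed=2)
        fid = wf.fiducials
        tdp_r = fid.loc[fid["label"] == LABEL_TDP, "r"].dropna().astype(int)
        amps = wf.samples[tdp_r.to_numpy()]
        signs = np.sign(amps)
        flips = np.count_nonzero(signs[:-1] * signs[1:] < 0)
        assert flips == len(amps) - 1  # strict alternation across the run

    def test_low_sampling_rate_rejected(self, yc_baseline_series):
        with pytest.raises(ValueError, match="250"):
            r.render_waveform(yc_baseline_series, fs_hz=100)

    def test_detection_recovers_all_fiducials_noiseless(self, yc_profile):
        s = r.make_beat_series(
            yc_profile, r.PhaseProtocol((("baseline", 30.0),)), seed=6)
        wf = r.render_waveform(s, fs_hz=1000, noise_sd_mv=0.0, seed=0)
        det = r.detect_r_peaks(wf)
        truth = wf.fiducials["r"].dropna().to_numpy() / wf.fs_hz
        tp, fp, fn = r.match_peaks(det, truth, tol_s=0.002)
        assert fp == 0 and fn == 0


class TestCohort:
    def test_zero_propensity_has_no_responders(self):
        p = r.GroupProfile(name="p0", rr_mean_ms=400.0, qt_mean_ms=200.0,
                           tdp_propensity=0.0)
        flags = r.responder_flags([p], 50, seed=3)
        assert not any(flags["p0"])

    def test_responder_incidence_matches_propensity(self):
        """n=1000 per group: simulated incidence within 3% of propensity."""
        profs = [r.GroupProfile(name=n, rr_mean_ms=400.0, qt_mean_ms=200.0,
                                tdp_propensity=p)
                 for n, p in (("YC", 0.83), ("AC", 0.18), ("CH", 0.21))]
        flags = r.responder_flags(profs, 1000, seed=7)
        for name, p in (("YC", 0.83), ("AC", 0.18), ("CH", 0.21)):
            assert abs(np.mean(flags[name]) - p) < 0.03

    def test_study_design_sizes(self, short_protocol):
        cohort = r.generate_cohort(r.default_profiles(), (12, 11, 14),
                                   seed=1, protocol=short_protocol,
                                   render=False)
        assert len(cohort.animals) == 37
        groups = [a.group for a in cohort.animals]
        assert (groups.count("YC"), groups.count("AC"),
                groups.count("CH")) == (12, 11, 14)

    def test_cohort_truth_consistent_with_labels(self, short_protocol):
        cohort = r.generate_cohort(r.default_profiles()[:1], 3, seed=2,
                                   protocol=short_protocol, render=False)
        for animal in cohort.animals:
            eps = r.classify_runs(animal.series.label,
                                  animal.series.beat_time_s)
            truth = animal.truth["events"]
            got = {(e.kind, e.start_index, e.n_beats) for e in eps}
            want = {(e["kind"], e["start_index"], e["n_beats"])
                    for e in truth}
            assert got == want
            has_tdp = any(e["kind"] == "TdP" for e in truth)
            assert has_tdp == animal.truth["responder"]

    def test_empty_profile_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            r.generate_cohort([], 3, seed=0)
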