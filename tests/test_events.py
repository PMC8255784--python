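"""Episode classification, inducibility/termination rules, incidence."""

import numpy as np
import pytest

import rabbitecg as r
from rabbitecg.events import (Episode, classify_runs, labels_from_waveform,
                              outcome_category, termination_check)


def _series(labels, rr_s=0.4):
    times = np.arange(1, len(labels) + 1) * rr_s
    return np.array(labels, dtype=object), times


class TestClassifyRuns:
    def test_isolated_ectopic_is_seb(self):
        labels, times = _series(["normal", "ectopic", "normal"])
        eps = classify_runs(labels, times)
        assert [(e.kind, e.n_beats) for e in eps] == [("SEB", 1)]

    def test_run_of_three_is_meb(self):
        labels, times = _series(["normal"] * 3 + ["ectopic"] * 3
                                + ["normal"] * 3)
        eps = classify_runs(labels, times)
        assert [(e.kind, e.n_beats) for e in eps] == [("MEB", 3)]

    def test_run_of_five_tdp_labels_is_tdp(self):
        labels, times = _series(["normal"] * 2 + ["tdp"] * 5 + ["normal"] * 2)
        eps = classify_runs(labels, times)
        assert [(e.kind, e.n_beats) for e in eps] == [("TdP", 5)]

    def test_long_ectopic_run_splits_into_mebs(self):
        labels, times = _series(["normal"] + ["ectopic"] * 9 + ["normal"])
        eps = classify_runs(labels, times)
        assert [e.kind for e in eps] == ["MEB", "MEB", "MEB"]
        assert sorted(e.n_beats for e in eps) == [2, 3, 4]

    def test_bigeminy_chains_alternating_singles(self):
        labels, times = _series(
            ["normal", "ectopic"] * 4 + ["normal"] * 3)
        eps = classify_runs(labels, times)
        assert [(e.kind, e.n_beats) for e in eps] == [("bigeminy", 4)]

    def test_two_alternations_stay_sebs(self):
        labels, times = _series(
            ["normal", "ectopic", "normal", "ectopic", "normal", "normal"])
        eps = classify_runs(labels, times)
        assert [e.kind for e in eps] == ["SEB", "SEB"]

    def test_unknown_label_rejected(self):
        labels, times = _series(["normal", "weird"])
        with pytest.raises(ValueError, match="unknown label"):
            classify_runs(labels, times)

    def test_every_beat_in_at_most_one_episode(self, yc_profile):
        s = r.make_beat_series(
            yc_profile, r.PhaseProtocol((("baseline", 300.0),)), seed=8)
        s2, _ = r.inject_ectopy(s, 2.0, 1.0, bigeminy=True, seed=9)
        eps = classify_runs(s2.label, s2.beat_time_s)
        claimed = set()
        for e in eps:
            stride = 2 if e.kind == "bigeminy" else 1
            beats = {e.start_index + stride * k for k in range(e.n_beats)}
            assert not beats & claimed
            claimed |= beats

    def test_label_mode_recovers_generator_truth_exactly(self, yc_profile,
                                                         short_protocol):
        cohort = r.generate_cohort(r.default_profiles(), (3, 3, 3), seed=4,
                                   protocol=short_protocol, render=False)
        for animal in cohort.animals:
            eps = classify_runs(animal.series.label,
                                animal.series.beat_time_s)
            got = {(e.kind, e.start_index, e.n_beats,
                    round(e.start_time_s, 9), round(e.end_time_s, 9))
                   for e in eps}
            want = {(e["kind"], e["start_index"], e["n_beats"],
                     round(e["start_time_s"], 9), round(e["end_time_s"], 9))
                    for e in animal.truth["events"]}
            assert got == want


class TestEpisodeInvariants:
    def test_tdp_needs_five_beats(self):
        with pytest.raises(ValueError, match=">= 5"):
            Episode("TdP", 0.0, 1.0, 4)

    def test_meb_needs_two_to_four(self):
        with pytest.raises(ValueError):
            Episode("MEB", 0.0, 1.0, 5)

    def test_end_before_start_rejected(self):
        with pytest.raises(ValueError):
            Episode("SEB", 2.0, 1.0, 1)


class TestTdpInducible:
    def test_three_short_episodes_inducible(self):
        eps = [Episode("TdP", 10.0 * k, 10.0 * k + 2.0, 6)
               for k in range(3)]
        assert r.tdp_inducible(eps)

    def test_single_11s_episode_inducible(self):
        assert r.tdp_inducible([Episode("TdP", 0.0, 11.0, 20)])

    def test_exactly_ten_seconds_not_inducible(self):
        eps = [Episode("TdP", 0.0, 10.0, 20),
               Episode("TdP", 50.0, 60.0, 20)]
        assert not r.tdp_inducible(eps)

    def test_non_tdp_episodes_ignored(self):
        eps = [Episode("MEB", 0.0, 100.0, 3)] * 5
        assert not r.tdp_inducible(eps)


class TestTerminationCheck:
    def test_persistent_tdp_terminates_after_20s(self):
        eps = [Episode("TdP", 2000.0, 2025.0, 60)]
        assert termination_check(eps) == pytest.approx(2020.0)

    def test_no_tdp_runs_to_protocol_end(self):
        assert termination_check([]) == pytest.approx(3600.0)

    def test_19s_episode_does_not_terminate_early(self):
        eps = [Episode("TdP", 100.0, 119.0, 50)]
        assert termination_check(eps) == pytest.approx(3600.0)


class TestOutcomeCategory:
    def test_no_episodes_is_no_arrhythmia(self):
        out = outcome_category([], animal_id="a")
        assert out.category == "no_arrhythmia"
        assert not out.inducible

    def test_meb_only_is_non_tdp(self):
        out = outcome_category([Episode("MEB", 1.0, 2.0, 3)])
        assert out.category == "non_tdp"
        assert out.meb_present and not out.seb_present

    def test_inducible_with_preceding_seb(self):
        eps = [Episode("SEB", 1.0, 1.0, 1)] + \
            [Episode("TdP", 10.0 + k, 12.0 + k, 6) for k in range(3)]
        out = outcome_category(eps)
        assert out.category == "tdp" and out.inducible
        assert out.seb_present

    def test_ectopy_after_tdp_onset_excluded_from_flags(self):
        eps = [Episode("TdP", 10.0 + k, 12.0 + k, 6) for k in range(3)]
        eps.append(Episode("SEB", 50.0, 50.0, 1))
        out = outcome_category(eps)
        assert out.category == "tdp"
        assert not out.seb_present


class TestIncidence:
    @pytest.mark.parametrize("k,n,pct", [(10, 12, 83), (2, 11, 18),
                                         (3, 14, 21), (7, 11, 64)])
    def test_reported_incidences(self, k, n, pct):
        assert r.incidence_from_counts(k, n) == (k, n, pct)

    def test_predicate_form(self):
        outcomes = [outcome_category([]) for _ in range(2)]
        outcomes.append(outcome_category([Episode("MEB", 0.0, 1.0, 2)]))
        k, n, pct = r.incidence(outcomes, lambda o: o.category == "non_tdp")
        assert (k, n, pct) == (1, 3, 33)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            r.incidence([], lambda o: True)


class TestWaveformMode:
    def test_waveform_mode_recovers_events(self):
        """Label inference from a rendered waveform recovers the injected
        episode inventory (F1 >= 0.95 at default noise)."""
        proto = r.PhaseProtocol((("dofetilide_high", 120.0),))
        prof = r.GroupProfile(name="x", rr_mean_ms=500.0, rr_sd_ms=15.0,
                              qt_mean_ms=250.0, qtc_jitter_ms=3.0)
        tp = n_truth = n_det = 0
        for seed in range(8):
            s = r.make_beat_series(prof, proto, seed=30 + seed)
            s2, ev = r.inject_ectopy(s, 1.0, 0.5, bigeminy=False,
                                     seed=60 + seed)
            s3, tev = r.inject_tdp(s2, 2, 8, seed=90 + seed)
            truth = r.refresh_event_times(ev, s3) + tev
            wf = r.render_waveform(s3, fs_hz=500, noise_sd_mv=0.01,
                                   seed=120 + seed)
            times, labels = labels_from_waveform(wf)
            eps = classify_runs(labels, times)
            used = [False] * len(eps)
            for t in truth:
                for i, e in enumerate(eps):
                    if (not used[i] and e.kind == t.kind
                            and abs(e.start_time_s - t.start_time_s) < 0.3):
                        used[i] = True
                        tp += 1
                        break
            n_truth += len(truth)
            n_det += len(eps)
        f1 = 2 * tp / (n_truth + n_det)
        assert f1 >= 0.95
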