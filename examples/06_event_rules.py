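"""Arrhythmia-event classification and the TdP inducibility rule.

Ectopy (single beats, runs of 2-4, bigeminy) and TdP episodes are injected
into a beat series; the run-length classifier recovers the inventory and
the inducibility rule (>= 3 TdP episodes, or one lasting > 10 s) plus the
incidence arithmetic reproduce the study's outcome bookkeeping.
"""

from collections import Counter

import rabbitecg as r

profile = r.default_profiles()[0]
series = r.make_beat_series(profile, seed=6)
series, _ = r.inject_ectopy(series, seb_rate=profile.seb_rate,
                            meb_rate=profile.meb_rate, bigeminy=True, seed=6)
series, _ = r.inject_tdp(series, n_episodes=3, episode_beats=9, seed=6)

episodes = r.classify_runs(series.label, series.beat_time_s)
print("episode inventory:", dict(Counter(e.kind for e in episodes)))

outcome = r.outcome_category(episodes, animal_id="YC01")
print(f"outcome: {outcome.category} (inducible={outcome.inducible}, "
      f"SEB={outcome.seb_present}, MEB={outcome.meb_present})")
print(f"termination: {r.termination_check(episodes):.0f} s "
      "(protocol end unless one episode persists 20 s)")

# reported incidence arithmetic: k of n as half-up integer percent
for group, k, n in (("YC", 10, 12), ("AC", 2, 11), ("CH", 3, 14)):
    print(f"  {group}: {k}/{n} -> {r.incidence_from_counts(k, n)[2]}% "
          "TdP inducibility")
z, p = r.two_sample_proportion_test(10, 12, 2, 11)
print(f"YC vs AC proportion test: z={z:.2f}, p={p:.4f}")
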