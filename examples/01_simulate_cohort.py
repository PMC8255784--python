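"""Simulate a rabbit TdP cohort and summarize the injected ground truth.

Generates the default three-group study design (12 young control, 11 adult
control, 14 cholesterol-fed animals) over a scaled-down four-phase drug
protocol and prints each group's TdP responder count alongside its
propensity.  The responder fractions fluctuate around the propensities
(0.83 / 0.18 / 0.21) because each animal's status is an independent draw.
"""

import rabbitecg as r

protocol = r.PhaseProtocol((("baseline", 320.0), ("methoxamine", 60.0),
                            ("dofetilide_low", 60.0),
                            ("dofetilide_high", 240.0)))
cohort = r.generate_cohort(r.default_profiles(), (12, 11, 14), seed=1,
                           protocol=protocol, render=False)

print(f"cohort of {len(cohort.animals)} animals")
for group, propensity in (("YC", 0.83), ("AC", 0.18), ("CH", 0.21)):
    animals = [a for a in cohort.animals if a.group == group]
    responders = sum(a.truth["responder"] for a in animals)
    events = sum(len(a.truth["events"]) for a in animals)
    print(f"  {group}: {responders}/{len(animals)} TdP responders "
          f"(propensity {propensity}), {events} injected arrhythmia events")
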