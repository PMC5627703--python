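"""Simulate a small cohort through a five-state natural-history model
and summarize who is in which state at selected ages.

The model describes progression from a healthy state (*normal*) through
a precursor lesion (*cin1*) to hidden disease (*occult*), which can
surface clinically (*symp*) or be caught and treated (*treated*); the
probability of surfacing is age-dependent.
"""

import io

from statesim import SimulationConfig, parse_stt, simulate_cohort, summarize, write_results

STT = """\
occult symp 12 20 0.05
occult symp 20 40 0.06
occult treated 12 80 0.07
normal cin1 12 80 0.2
cin1 occult 12 80 0.3
"""

model = parse_stt(STT)
config = SimulationConfig(startage=12, stopage=80, interval=2, number=1000,
                          initialstate="normal", seed=5489)
cohort = simulate_cohort(model, config)

buf = io.StringIO()
write_results(cohort, buf)
print("first rows of the results matrix (one line per individual):")
print("\n".join(buf.getvalue().splitlines()[:4]))

for age in (12, 40, 80):
    print(f"\nstate counts at age {age} (of {config.number} individuals):")
    print(summarize(cohort, age))

print("\nEveryone starts in 'normal' at age 12; by age 80 most of the cohort")
print("has progressed to the absorbing 'symp' or 'treated' states.")
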