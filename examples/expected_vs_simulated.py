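"""Compare Monte Carlo state frequencies with the exact analytic law.

A single rule moves individuals from *normal* to *cin1* with per-step
probability 0.5, so the exact share still in *normal* after k steps is
0.5**k — a geometric decay the simulation should track within binomial
noise.
"""

from statesim import SimulationConfig, expected_counts, parse_stt, simulate_cohort

model = parse_stt("normal cin1 12 80 0.5")
config = SimulationConfig(startage=20, stopage=24, interval=1, number=100_000,
                          initialstate="normal", seed=5489)

cohort = simulate_cohort(model, config)
exact = expected_counts(model, config)

print(f"{'age':>4} {'simulated cin1':>15} {'expected cin1':>15}")
for age in cohort.ages:
    sim = cohort.counts_at(age).get("cin1", 0)
    print(f"{age:4.0f} {sim:15d} {exact.loc[age, 'cin1']:15.1f}")

print("\nExpected counts are cohort size times the exact probability mass")
print("1 - 0.5**k after k steps; the simulated column agrees to ~0.5%.")
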