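"""Validate transition tables: explicit stay probabilities and the
per-band sum-to-at-most-1 check.

Spelling out the implicit stay probability as an explicit self
transition lets the validator confirm each age band's outgoing
probabilities account for exactly the whole unit interval.
"""

from statesim import parse_stt, validate_model

GOOD = """\
occult symp 12 20 0.05
occult treated 12 80 0.07
occult occult 12 20 0.88
"""

BAD = """\
normal cin1 12 80 0.2
normal normal 12 80 0.9
"""

print("table with an explicit stay probability filling the band exactly:")
print(validate_model(parse_stt(GOOD)))

print("\ntable whose band totals 1.1:")
print(validate_model(parse_stt(BAD)))

print("\nThe second table is rejected: on ages [12, 80) state 'normal'")
print("claims more outgoing probability than exists.")
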