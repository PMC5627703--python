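# Methods

## Model

`statesim` simulates a discrete-time, age-inhomogeneous Markov chain
over a finite set of named states. The model is specified extensionally
as transition rules `source sink age_min age_max prob`: for an
individual currently in `source` whose age lies in `[age_min, age_max)`,
the probability of moving to `sink` during one time interval is `prob`.
The Markov property holds by construction — the next state depends only
on the current state and current age. History effects (e.g. "once
treated, relapse is less likely") must be encoded as extra states.

Age bands are half-open: a rule with band `12 20` is active for
`12 <= age < 20`, so the shared endpoint 20 belongs to the next band.
This convention is applied uniformly, including the top band — at
`age == age_max` a rule is inactive. The age used to select rules for
the transition *into* recorded age `a_{k+1}` is `a_k`, the age at the
start of the step.

Stay probability is implicit: for state *s* at age *a* it is 1 minus
the sum of the active non-self outgoing probabilities. A table may also
carry explicit self-transition lines (`occult occult 12 20 0.88`).
These are bookkeeping: they participate in validation (see below) but
are semantically merged with the implicit residual — both mean "stay" —
so writing them out never changes the simulated law. In the engine this
is enforced by never laying self rules as sampling intervals; laying
them would double-count stay mass against the residual.

Overlapping age ranges for the same source–sink pair are legal and
additive (they are independent rules); only exact duplicate lines are
rejected, as a likely copy-paste error. Ages and probabilities parse as
arbitrary decimals, state names are case-sensitive whitespace-free
tokens, and line order is irrelevant to the model's law (it is kept
only as the deterministic order in which rules are laid on [0, 1)).

## Validation

For each source state, the distinct rule endpoints cut the age axis
into *elementary bands* on which the active rule set is constant.
Validation sums the active probabilities — explicit self transitions
included — on every elementary band and reports an error naming the
state, band and total whenever a sum exceeds `1 + 1e-9`. The tolerance
absorbs the decimal-to-binary representation error of short decimal
inputs such as 0.05 + 0.07 + 0.88; genuinely oversubscribed bands
exceed it by orders of magnitude. Validation findings are report
entries, not exceptions, so a front end can show all of them at once.

## Simulation engine

Each individual walks the recorded age grid `startage, startage +
interval, …, stopage`. At each step one uniform variate *u* is drawn
and mapped to a transition by inverse transform over the cumulative
probabilities of the active non-self rules in file order: rule *i*
occupies `[c_{i-1}, c_i)` of the running sum, the mapping is
left-closed (`u < c` selects, `u >= c` falls through), and any *u* at
or beyond the final sum means "stay". A state with no active rules —
an absorbing state, or an age outside every band — always stays.

Exactly one variate is consumed per individual per step, even in
absorbing states. Combined with a single shared MT19937 stream, seeded
once and never reset between individuals, this makes the variate count
depend only on cohort size and grid length, so no individual's path can
perturb another's draws and the whole cohort is reproducible from the
seed alone. The generator is NumPy's MT19937 bit generator with the
standard 53-bit double mapping to [0, 1). Internally the cohort is
advanced one age step at a time over a pre-drawn variate block; because
the block is filled in sequence order, this consumes the identical
stream as per-individual stepping, and a test asserts that equality.
Bit-compatibility with other MT19937-based implementations depends on
their raw-output-to-double mapping and is not promised; internal
reproducibility is.

The default seed is 5489, the conventional MT19937 default, overridable
per run; `seed:clock` derives a seed from the system clock
(`time_ns() mod 2^31`) for deliberately non-reproducible runs.

## Analytic oracle

The exact counterpart of the engine is forward propagation of the
one-step matrices: row *s* of the matrix at age *a* has off-diagonal
entries equal to the summed active non-self probabilities and diagonal
equal to the stay probability; never-source states get identity rows.
The initial point mass is multiplied through the matrices of successive
recorded ages, yielding the exact state distribution at each age;
expected counts are cohort size times mass. Matrices are built per
recorded age, not per elementary band, because the simulation only
evaluates rules at recorded ages — bands finer than the grid are
invisible to it, and the oracle must match that behaviour exactly. The
representation is dense; models in this format have tens of states at
most, so sparsity machinery is declined.

For a single rule with probability *p* active over the whole span, the
propagated probability of having left the initial state after *k* steps
is the closed form `1 − (1−p)^k`, which both the analytic and the
Monte Carlo paths are tested against (p = 0.5 gives 50% after one step
and 75% after two).

## Configuration

The config file is `key:value` lines. The four cohort-geometry keys
(`startage`, `stopage`, `interval`, `number`) are required — silent
defaults would mask user error. The initial state defaults to `normal`
and must be a *source* state of the model: starting in a state with no
outgoing rules is always a specification mistake. The age span must be
a whole number of intervals; a ragged final step is an error rather
than a truncation. Both parsers trim whitespace, tolerate CRLF line
endings, and skip `#` comment lines (a documented extension that keeps
fixture files readable).

## Synthetic fixtures

`generate_fixture` builds random valid models for property testing:
generic state names, random integer-endpoint half-open bands inside a
span, and probabilities rescaled per source so that no elementary band
exceeds a total of 0.95 — every fixture therefore validates and retains
genuine stay mass, exercising both movement and staying. Configurations
draw 3–50 recorded ages on a unit or two-unit grid and start in a
random source state. Fixtures are deterministic in their seed. What
they emulate is the structural variety of hand-written tables (band
overlap, multiple sinks, absorbing states); what they do not emulate is
calibrated epidemiology — passing the oracle-equivalence tests shows the
sampler realizes the specified law, not that any particular disease
model is realistic.

## Test and verification sizes

The distributional tests compare empirical frequencies with the exact
propagated masses under per-state 4σ binomial envelopes: 50 random
models at 100,000 individuals each in the end-to-end suite, plus
smaller hypothesis-driven sweeps (derandomized) for parsing, band
algebra and stream accounting. The headline verification experiment —
one rule at p = 0.5 — is run at n = 1,000 and n = 1,000,000 for one
step (3σ envelopes of ±4.7 and ±0.15 percentage points around 50%) and
at n = 100,000 for two steps against the exact 75%.

## Known limitations

- No continuous-time rates or competing-risk hazard conversion; inputs
  are per-interval probabilities, and rescaling the time unit requires
  the user to adjust ages and probabilities consistently.
- No staggered cohort entry, per-individual covariates, mortality
  weighting or screening overlays; those belong to downstream
  applications built on these primitives.
- Individuals are simulated on one shared stream by design; parallel
  simulation would require a documented per-individual substream scheme
  and is deliberately not offered.
- The results writer emits standard CSV without the trailing comma some
  older tooling in this format family appends; the reader accepts both.
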