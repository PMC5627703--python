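"""Monte Carlo cohort simulation.

Each individual's trajectory is a walk over the recorded age grid.  One
uniform variate is drawn per individual per age step — always exactly
one, even in absorbing states or at ages outside every rule band — and
mapped to a transition by laying the active non-self rules end-to-end
on [0, 1) in file order: rule i occupies the half-open interval
[c_{i-1}, c_i) of the running probability sum, and any draw at or above
the final sum means "stay".  Explicit self-transition rules are never
laid as intervals; their mass is part of the residual stay probability,
so writing them out changes validation but not the simulated law.

All individuals share a single MT19937 stream, seeded once, that is not
reset between individuals.  Because the per-individual variate count
depends only on the age grid, one individual's path can never perturb
another's draws, and the whole cohort is reproducible from the seed
alone.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .config import CLOCK_SEED, SimulationConfig, recorded_ages
from .model import TransitionModel, validate_model

__all__ = [
    "RandomStream",
    "Trajectory",
    "CohortResult",
    "resolve_seed",
    "step",
    "simulate_individual",
    "simulate_cohort",
]


def resolve_seed(seed: int | str) -> int:
    """Turn a configured seed into a concrete integer: ``clock`` draws
    from the system clock, anything else must already be an integer."""
    if seed == CLOCK_SEED:
        return time.time_ns() % (2**31)
    return int(seed)


class RandomStream:
    """A seeded MT19937 uniform stream.

    Variates are 53-bit doubles in [0, 1).  ``position`` counts consumed
    variates; two streams with equal seeds produce identical sequences
    on every platform.
    """

    def __init__(self, seed: int):
        self.seed = int(seed)
        self.position = 0
        self._gen = np.random.Generator(np.random.MT19937(self.seed))

    def next_uniform(self) -> float:
        self.position += 1
        return float(self._gen.random())

    def uniforms(self, shape) -> np.ndarray:
        """A block of variates in sequence order (row-major: the first
        row holds the first draws)."""
        block = self._gen.random(size=shape)
        self.position += block.size
        return block


@dataclass(frozen=True)
class Trajectory:
    """One individual's recorded states, one per recorded age."""

    id: int
    states: tuple[str, ...]


class CohortResult:
    """The outcome of simulating a cohort.

    States are stored as one integer-coded matrix of shape
    (number, len(ages)); ``trajectories`` materializes the per-individual
    view on demand and ``counts_at`` aggregates a column without it.
    """

    def __init__(self, ages: list[float], state_names: list[str], codes: np.ndarray,
                 config: SimulationConfig | None = None):
        if codes.ndim != 2 or codes.shape[1] != len(ages):
            raise ValueError("codes must be (individuals, recorded ages)")
        self.ages = list(ages)
        self.state_names = list(state_names)
        self.codes = codes
        self.config = config

    @property
    def number(self) -> int:
        return self.codes.shape[0]

    @cached_property
    def trajectories(self) -> list[Trajectory]:
        names = self.state_names
        return [
            Trajectory(id=i + 1, states=tuple(names[c] for c in row))
            for i, row in enumerate(self.codes)
        ]

    def counts_at(self, age: float) -> dict[str, int]:
        """How many individuals are in each state at a recorded age."""
        try:
            col = self.ages.index(age)
        except ValueError:
            raise KeyError(f"age {age:g} is not a recorded age") from None
        counts = np.bincount(self.codes[:, col], minlength=len(self.state_names))
        return {s: int(n) for s, n in zip(self.state_names, counts) if n > 0}

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CohortResult)
            and self.ages == other.ages
            and self.state_names == other.state_names
            and np.array_equal(self.codes, other.codes)
        )


def step(model: TransitionModel, state: str, age: float, u: float) -> str:
    """One transition of one individual given the uniform draw ``u``.

    The active non-self rules, in file order, partition [0, 1) by their
    running probability sum; the mapping is left-closed (``u < c``
    selects, ``u >= c`` falls through).  A state with no active rules
    always returns itself.
    """
    if state not in model.states:
        raise KeyError(f"unknown state: {state!r}")
    c = 0.0
    for rule in model.rules:
        if rule.source != state or rule.is_self or not rule.active_at(age):
            continue
        c += rule.prob
        if u < c:
            return rule.sink
    return state


def simulate_individual(model: TransitionModel, config: SimulationConfig,
                        stream: RandomStream, id: int) -> Trajectory:
    """Walk one individual over the recorded age grid, consuming exactly
    one variate per step regardless of the states visited."""
    ages = recorded_ages(config)
    states = [config.initialstate]
    for k in range(len(ages) - 1):
        u = stream.next_uniform()
        states.append(step(model, states[-1], ages[k], u))
    return Trajectory(id=id, states=tuple(states))


def _step_kernels(model: TransitionModel, ages: list[float]):
    """Per step and per state: cumulative interval bounds and the coded
    sinks they map to, matching the scalar ``step`` arithmetic."""
    index = {s: i for i, s in enumerate(model.states)}
    kernels = []
    for age in ages[:-1]:
        per_state = []
        for s in model.states:
            probs, sinks = [], []
            for rule in model.rules:
                if rule.source != s or rule.is_self or not rule.active_at(age):
                    continue
                probs.append(rule.prob)
                sinks.append(index[rule.sink])
            per_state.append((np.cumsum(probs) if probs else np.empty(0),
                              np.asarray(sinks, dtype=np.intp)))
        kernels.append(per_state)
    return kernels


def simulate_cohort(model: TransitionModel, config: SimulationConfig,
                    seed: int | str | None = None) -> CohortResult:
    """Simulate ``config.number`` individuals sharing one seeded stream.

    Individuals are simulated one after the other without resetting the
    generator; the total number of variates consumed is exactly
    ``number * n_steps``.  Internally the cohort is advanced one age
    step at a time over pre-drawn variates, which consumes the identical
    stream sequence as per-individual stepping.

    ``seed`` overrides ``config.seed`` when given.
    """
    report = validate_model(model)
    if not report.ok:
        raise ValueError(f"model failed validation:\n{report}")
    if not model.rules:
        raise ValueError("model has no rules; nothing to simulate")
    if config.initialstate not in model.source_states:
        raise ValueError(f"initial state {config.initialstate!r} is not a source state")

    ages = recorded_ages(config)
    n, n_steps = config.number, len(ages) - 1
    stream = RandomStream(resolve_seed(config.seed if seed is None else seed))
    draws = stream.uniforms((n, n_steps))

    kernels = _step_kernels(model, ages)
    index = {s: i for i, s in enumerate(model.states)}
    codes = np.empty((n, len(ages)), dtype=np.intp)
    codes[:, 0] = index[config.initialstate]
    current = codes[:, 0].copy()
    for k in range(n_steps):
        u = draws[:, k]
        nxt = current.copy()
        for s in np.unique(current):
            cum, sinks = kernels[k][s]
            if cum.size == 0:
                continue
            mask = current == s
            pos = np.searchsorted(cum, u[mask], side="right")
            moved = pos < cum.size
            nxt[mask] = np.where(moved, sinks[np.minimum(pos, cum.size - 1)], s)
        current = nxt
        codes[:, k + 1] = current
    return CohortResult(ages, model.states, codes, config=config)
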