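"""Exact marginal state distributions by forward matrix propagation.

For each recorded age the model defines a row-stochastic one-step
transition matrix: off-diagonal entries are the summed probabilities of
the active non-self rules, the diagonal is the stay probability, and a
state never acting as a source gets an identity row.  Propagating the
initial point mass through these matrices gives the exact distribution
of the simulated chain at every recorded age — the deterministic twin of
the Monte Carlo engine and the oracle its output is tested against.

Matrices are built per recorded age, not per elementary band: the
simulation only ever evaluates rules at recorded ages, so bands finer
than the age grid are invisible to it, and the oracle must match that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig, recorded_ages
from .model import TransitionModel, stay_probability

__all__ = [
    "TransitionMatrix",
    "StateDistribution",
    "transition_matrix",
    "propagate",
    "expected_counts",
]


@dataclass(frozen=True)
class TransitionMatrix:
    """One-step operator applying at one age; entry (i, j) is the
    probability of moving from states[i] to states[j]."""

    age: float
    states: tuple[str, ...]
    matrix: np.ndarray

    def row(self, state: str) -> dict[str, float]:
        i = self.states.index(state)
        return {s: float(p) for s, p in zip(self.states, self.matrix[i])}


@dataclass(frozen=True)
class StateDistribution:
    age: float
    mass: dict[str, float]

    def __getitem__(self, state: str) -> float:
        return self.mass.get(state, 0.0)


def transition_matrix(model: TransitionModel, age: float) -> TransitionMatrix:
    """Build the exact one-step matrix at ``age``.

    Multiple rules for the same source-sink pair whose bands overlap add;
    explicit self-transitions are folded into the diagonal, which always
    equals ``stay_probability``.
    """
    states = list(model.states)
    index = {s: i for i, s in enumerate(states)}
    m = np.zeros((len(states), len(states)))
    for rule in model.rules:
        if rule.is_self or not rule.active_at(age):
            continue
        m[index[rule.source], index[rule.sink]] += rule.prob
    for s in states:
        m[index[s], index[s]] = stay_probability(model, s, age)
    return TransitionMatrix(age=age, states=tuple(states), matrix=m)


def propagate(model: TransitionModel, config: SimulationConfig) -> list[StateDistribution]:
    """Exact state distribution at every recorded age, starting from a
    point mass on the configured initial state."""
    ages = recorded_ages(config)
    states = list(model.states)
    v = np.zeros(len(states))
    v[states.index(config.initialstate)] = 1.0
    out = [StateDistribution(ages[0], dict(zip(states, v)))]
    for age_from, age_to in zip(ages, ages[1:]):
        v = v @ transition_matrix(model, age_from).matrix
        out.append(StateDistribution(age_to, {s: float(p) for s, p in zip(states, v)}))
    return out


def expected_counts(model: TransitionModel, config: SimulationConfig) -> pd.DataFrame:
    """Expected number of individuals per state at each recorded age:
    cohort size times the exact mass.  Rows are recorded ages, columns
    model states; every row sums to ``config.number``."""
    dists = propagate(model, config)
    table = pd.DataFrame(
        [{s: config.number * d.mass.get(s, 0.0) for s in model.states} for d in dists],
        index=pd.Index([d.age for d in dists], name="age"),
    )
    return table
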