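"""Results files, per-age summaries, and synthetic test fixtures.

The results layout is a plain CSV: a header row ``ID,<age>,<age>,...``
followed by one row per individual, the 1-based individual id and then
the bare state name at each recorded age.  The writer emits standard
CSV; the reader additionally tolerates a trailing comma per line, which
older tooling in this format family emits.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np

from .config import SimulationConfig
from .engine import CohortResult
from .model import TransitionModel, TransitionRule, validate_model, elementary_bands

__all__ = [
    "SummaryTable",
    "ResultsFormatError",
    "write_results",
    "read_results",
    "summarize",
    "write_summary",
    "generate_fixture",
]


class ResultsFormatError(ValueError):
    pass


@dataclass(frozen=True)
class SummaryTable:
    """State counts in one recorded-age column; counts sum to the
    number of individuals."""

    age: float
    counts: dict[str, int]

    def __str__(self) -> str:
        return "\n".join(f"{n:7d} {s}" for s, n in sorted(self.counts.items()))


def _fmt_age(age: float) -> str:
    """Integer-valued ages print without a decimal point."""
    return str(int(age)) if float(age) == int(age) else f"{age:g}"


def write_results(cohort: CohortResult, destination) -> None:
    """Write a cohort to ``destination`` (path or text file object) in
    the results CSV layout, rows in id order."""
    if hasattr(destination, "write"):
        _write_results_fh(cohort, destination)
    else:
        with open(destination, "w", encoding="utf-8", newline="") as fh:
            _write_results_fh(cohort, fh)


def _write_results_fh(cohort: CohortResult, fh) -> None:
    fh.write("ID," + ",".join(_fmt_age(a) for a in cohort.ages) + "\n")
    names = cohort.state_names
    for i, row in enumerate(cohort.codes, start=1):
        fh.write(f"{i}," + ",".join(names[c] for c in row) + "\n")


def read_results(source) -> CohortResult:
    """Read a results file back into a cohort table.

    The configuration that produced the file is not recoverable, so the
    returned cohort has ``config=None``.  Ragged rows, non-integer or
    duplicate ids, and a non-``ID`` header are errors.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source, encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    lines = [ln.rstrip("\r") for ln in lines if ln.strip()]
    if not lines:
        raise ResultsFormatError("empty results file")

    header = _split_row(lines[0])
    if header[0] != "ID":
        raise ResultsFormatError(f"header must start with 'ID', got {header[0]!r}")
    try:
        ages = [float(a) for a in header[1:]]
    except ValueError:
        raise ResultsFormatError(f"non-numeric age in header: {lines[0]!r}") from None

    names: list[str] = []
    index: dict[str, int] = {}
    seen_ids: set[int] = set()
    codes = np.empty((len(lines) - 1, len(ages)), dtype=np.intp)
    for row_no, line in enumerate(lines[1:], start=2):
        fields = _split_row(line)
        if len(fields) != 1 + len(ages):
            raise ResultsFormatError(
                f"line {row_no}: expected {1 + len(ages)} fields, got {len(fields)}"
            )
        try:
            ind = int(fields[0])
        except ValueError:
            raise ResultsFormatError(f"line {row_no}: non-integer id {fields[0]!r}") from None
        if ind in seen_ids:
            raise ResultsFormatError(f"line {row_no}: duplicate id {ind}")
        seen_ids.add(ind)
        for j, state in enumerate(fields[1:]):
            if state not in index:
                index[state] = len(names)
                names.append(state)
            codes[row_no - 2, j] = index[state]
    return CohortResult(ages, names, codes, config=None)


def _split_row(line: str) -> list[str]:
    fields = line.split(",")
    if fields and fields[-1] == "":  # tolerated trailing comma
        fields.pop()
    return fields


def summarize(results: CohortResult, age: float) -> SummaryTable:
    """Count individuals per state in one recorded-age column — the
    programmatic form of cutting the column and piping through
    ``sort | uniq -c``."""
    return SummaryTable(age=age, counts=results.counts_at(age))


def write_summary(results: CohortResult, destination) -> None:
    """Export per-age state counts as a CSV with columns age,state,count."""
    rows = ["age,state,count"]
    for age in results.ages:
        for state, count in sorted(results.counts_at(age).items()):
            rows.append(f"{_fmt_age(age)},{state},{count}")
    text = "\n".join(rows) + "\n"
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        with open(destination, "w", encoding="utf-8") as fh:
            fh.write(text)


def generate_fixture(
    n_states: int = 4,
    n_rules: int = 6,
    age_span: tuple[float, float] = (0.0, 100.0),
    seed: int = 0,
    number: int = 100,
) -> tuple[TransitionModel, SimulationConfig]:
    """Generate a random valid model and matching configuration.

    States get generic names ``s0..s{n-1}``; rules get random half-open
    integer-endpoint bands inside ``age_span`` and probabilities that are
    rescaled per source so every elementary band sums to at most 0.95
    (leaving genuine stay mass).  The configuration records between 3 and
    50 ages on a unit or two-unit grid inside the span and starts in a
    random source state.  Identical arguments give identical fixtures.
    """
    if n_states < 2 or n_rules < 1:
        raise ValueError("need at least 2 states and 1 rule")
    lo, hi = age_span
    if not (hi - lo >= 2):
        raise ValueError("age_span must cover at least 2 age units")
    rng = np.random.Generator(np.random.MT19937(seed))
    states = [f"s{i}" for i in range(n_states)]

    rules: list[TransitionRule] = []
    seen: set[tuple] = set()
    attempts = 0
    while len(rules) < n_rules:
        attempts += 1
        if attempts > 100 * n_rules:
            raise ValueError("could not generate the requested number of distinct rules")
        source = states[int(rng.integers(0, n_states))]
        sink = states[int(rng.integers(0, n_states))]
        a, b = sorted(rng.choice(np.arange(int(lo), int(hi) + 1), size=2, replace=False))
        prob = float(np.round(rng.uniform(0.01, 0.5), 4))
        key = (source, sink, float(a), float(b), prob)
        if key in seen:
            continue
        seen.add(key)
        rules.append(TransitionRule(source, sink, float(a), float(b), prob, len(rules) + 1))

    model = TransitionModel.from_rules(rules)
    # rescale each source so no elementary band exceeds total probability 0.95
    scaled: list[TransitionRule] = []
    for rule in rules:
        peak = max(
            sum(r.prob for r in band.active)
            for band in elementary_bands(model, rule.source)
        )
        factor = 0.95 / peak if peak > 0.95 else 1.0
        scaled.append(replace(rule, prob=rule.prob * factor))
    model = TransitionModel.from_rules(scaled)
    assert validate_model(model).ok

    n_ages = int(rng.integers(3, 51))
    interval = float(rng.choice([1.0, 2.0]))
    span_needed = (n_ages - 1) * interval
    start_max = max(int(lo), int(hi - span_needed))
    startage = float(rng.integers(int(lo), start_max + 1))
    config = SimulationConfig(
        startage=startage,
        stopage=startage + span_needed,
        interval=interval,
        number=number,
        initialstate=model.source_states[int(rng.integers(0, len(model.source_states)))],
        seed=int(rng.integers(0, 2**31)),
    )
    return model, config
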