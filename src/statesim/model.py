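"""State-transition tables: parsing, representation, and validation.

A model is a flat list of transition rules, one per line of the input
table.  Each rule says: an individual in ``source``, whose current age
lies in the half-open band ``[age_min, age_max)``, moves to ``sink``
with probability ``prob`` during one time interval.  Whatever outgoing
probability is not claimed by the active rules is the implicit
probability of staying put; an explicit ``source source ...`` line may
spell out (part of) that stay probability, in which case it counts
toward the per-band total that validation checks against 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "TransitionRule",
    "TransitionModel",
    "ElementaryBand",
    "ValidationIssue",
    "ValidationReport",
    "SttParseError",
    "parse_stt",
    "elementary_bands",
    "validate_model",
    "outgoing",
    "stay_probability",
]

#: slack allowed on per-band probability totals, to absorb the
#: decimal-to-binary representation error of short decimals such as
#: 0.05 + 0.07 + 0.88.
SUM_TOLERANCE = 1e-9


class SttParseError(ValueError):
    """Raised when a transition table cannot be parsed.

    Collects every offending line so the user can fix them in one pass.
    """

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid state transition table:\n" + "\n".join(self.problems))


@dataclass(frozen=True)
class TransitionRule:
    """One line of the transition table.

    ``age_min`` is inclusive and ``age_max`` exclusive: a rule with band
    12 20 is active for ages ``12 <= age < 20``.  ``line_no`` records the
    1-based position in the source file; it only matters as the
    deterministic tie-break order in which rules are laid out on [0, 1).
    """

    source: str
    sink: str
    age_min: float
    age_max: float
    prob: float
    line_no: int

    @property
    def is_self(self) -> bool:
        return self.source == self.sink

    def active_at(self, age: float) -> bool:
        return self.age_min <= age < self.age_max

    def __str__(self) -> str:
        return f"{self.source} {self.sink} {_fmt(self.age_min)} {_fmt(self.age_max)} {_fmt(self.prob)}"


def _fmt(x: float) -> str:
    return f"{x:g}"


@dataclass
class TransitionModel:
    """A validated-parseable rule set plus its state inventory.

    ``states`` lists every name appearing as a source or sink, in order
    of first appearance; ``source_states`` is the subset ever appearing
    in the source column (only these can be left, and only these are
    legal initial states).
    """

    rules: list[TransitionRule]
    states: list[str] = field(default_factory=list)
    source_states: list[str] = field(default_factory=list)

    @classmethod
    def from_rules(cls, rules: list[TransitionRule]) -> "TransitionModel":
        states: list[str] = []
        sources: list[str] = []
        for r in rules:
            for name in (r.source, r.sink):
                if name not in states:
                    states.append(name)
            if r.source not in sources:
                sources.append(r.source)
        return cls(rules=list(rules), states=states, source_states=sources)

    def rules_from(self, source: str) -> list[TransitionRule]:
        return [r for r in self.rules if r.source == source]

    def __contains__(self, state: str) -> bool:
        return state in self.states


@dataclass(frozen=True)
class ElementaryBand:
    """A maximal half-open age interval over which the active rule set
    of one source state is constant.  The unit at which the sum-to-at-
    most-1 check applies."""

    lo: float
    hi: float
    active: tuple[TransitionRule, ...]


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" or "warning"
    source: str
    band: tuple[float, float]
    message: str
    total: float


@dataclass
class ValidationReport:
    issues: list[ValidationIssue]

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def __str__(self) -> str:
        if self.ok and not self.issues:
            return "model ok"
        return "\n".join(
            f"{i.severity}: state '{i.source}', ages [{_fmt(i.band[0])}, {_fmt(i.band[1])}): {i.message}"
            for i in self.issues
        )


def parse_stt(text: str) -> TransitionModel:
    """Parse a transition table from raw file content.

    One rule per non-blank line, five whitespace-separated fields:
    ``source sink age_min age_max probability``.  CRLF endings are
    tolerated and lines starting with ``#`` are skipped.  Line order is
    irrelevant to the model's law but preserved for reproducible
    tie-breaking.

    Raises
    ------
    SttParseError
        listing every malformed line: wrong field count, non-numeric
        age or probability, probability outside [0, 1], empty age band,
        or an exact duplicate line.
    """
    rules: list[TransitionRule] = []
    problems: list[str] = []
    seen: dict[tuple, int] = {}
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\r").strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 5:
            problems.append(f"line {line_no}: expected 5 fields, got {len(fields)}: {line!r}")
            continue
        source, sink, s_min, s_max, s_prob = fields
        try:
            age_min, age_max, prob = float(s_min), float(s_max), float(s_prob)
        except ValueError:
            problems.append(f"line {line_no}: non-numeric age or probability: {line!r}")
            continue
        if not 0.0 <= prob <= 1.0:
            problems.append(f"line {line_no}: probability {s_prob} outside [0, 1]")
            continue
        if not age_min < age_max:
            problems.append(f"line {line_no}: empty age band [{s_min}, {s_max})")
            continue
        key = (source, sink, age_min, age_max, prob)
        if key in seen:
            problems.append(f"line {line_no}: exact duplicate of line {seen[key]}")
            continue
        seen[key] = line_no
        rules.append(TransitionRule(source, sink, age_min, age_max, prob, line_no))
    if problems:
        raise SttParseError(problems)
    return TransitionModel.from_rules(rules)


def load_stt(path) -> TransitionModel:
    """Read and parse a transition table file."""
    with open(path, encoding="utf-8") as fh:
        return parse_stt(fh.read())


def elementary_bands(model: TransitionModel, source: str) -> list[ElementaryBand]:
    """Decompose the age axis for one source state.

    The distinct rule endpoints cut the axis into consecutive half-open
    bands; each rule is attached to every band it fully covers (rules
    can only cover bands fully, since their own endpoints are cut
    points).  Bands with no active rule are omitted.
    """
    if source not in model.states:
        raise KeyError(f"unknown state: {source!r}")
    rules = model.rules_from(source)
    points = sorted({p for r in rules for p in (r.age_min, r.age_max)})
    bands: list[ElementaryBand] = []
    for lo, hi in zip(points, points[1:]):
        active = tuple(r for r in rules if r.age_min <= lo and hi <= r.age_max)
        if active:
            bands.append(ElementaryBand(lo, hi, active))
    return bands


def validate_model(model: TransitionModel) -> ValidationReport:
    """Check that no source state's outgoing probability, explicit
    self-transitions included, exceeds 1 on any elementary age band.

    Validation problems are report entries, never exceptions; ``report.ok``
    is False iff an error was found.
    """
    issues: list[ValidationIssue] = []
    for source in model.source_states:
        for band in elementary_bands(model, source):
            total = sum(r.prob for r in band.active)
            if total > 1.0 + SUM_TOLERANCE:
                issues.append(
                    ValidationIssue(
                        severity="error",
                        source=source,
                        band=(band.lo, band.hi),
                        message=f"outgoing probabilities total {total:g} > 1",
                        total=total,
                    )
                )
    return ValidationReport(issues)


def outgoing(model: TransitionModel, state: str, age: float) -> list[tuple[str, float]]:
    """The (sink, prob) pairs of rules active for ``state`` at ``age``,
    in file order.  Explicit self-transitions are returned like any
    other rule.  Empty if the state is never a source or the age falls
    outside every band (both mean: certain to stay)."""
    if state not in model.states:
        raise KeyError(f"unknown state: {state!r}")
    return [(r.sink, r.prob) for r in model.rules if r.source == state and r.active_at(age)]


def stay_probability(model: TransitionModel, state: str, age: float) -> float:
    """Probability of remaining in ``state`` for one step at ``age``:
    1 minus the active non-self outgoing probabilities.  An explicit
    self-transition rule is part of "stay", so its mass is included."""
    if state not in model.states:
        raise KeyError(f"unknown state: {state!r}")
    leave = sum(p for sink, p in outgoing(model, state, age) if sink != state)
    return 1.0 - leave
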