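"""Simulation configuration: the ``key:value`` config file.

Recognized keys: ``startage``, ``stopage``, ``interval`` (age step per
transition), ``number`` (cohort size), ``initialstate`` and ``seed``.
The four cohort-geometry keys are required; the initial state defaults
to ``normal`` and the seed to the conventional Mersenne-Twister default
5489.  ``seed:clock`` requests time-based seeding so that repeated runs
differ.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import TransitionModel

__all__ = [
    "SimulationConfig",
    "ConfigError",
    "parse_config",
    "recorded_ages",
    "DEFAULT_SEED",
    "CLOCK_SEED",
]

DEFAULT_SEED = 5489
DEFAULT_INITIAL_STATE = "normal"
#: sentinel value of ``seed`` selecting system-clock seeding
CLOCK_SEED = "clock"

_NUMERIC_KEYS = ("startage", "stopage", "interval", "number")
_ALL_KEYS = _NUMERIC_KEYS + ("initialstate", "seed")

#: relative slack when checking that the age span is a whole number of intervals
_GRID_TOLERANCE = 1e-9


class ConfigError(ValueError):
    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid config:\n" + "\n".join(self.problems))


@dataclass(frozen=True)
class SimulationConfig:
    startage: float
    stopage: float
    interval: float
    number: int
    initialstate: str = DEFAULT_INITIAL_STATE
    seed: int | str = DEFAULT_SEED

    def __post_init__(self):
        problems = _geometry_problems(self.startage, self.stopage, self.interval, self.number)
        if problems:
            raise ConfigError(problems)

    @property
    def n_steps(self) -> int:
        return round((self.stopage - self.startage) / self.interval)

    def render(self) -> str:
        """The config file text that parses back to this configuration."""
        lines = [
            f"startage:{self.startage:g}",
            f"stopage:{self.stopage:g}",
            f"interval:{self.interval:g}",
            f"number:{self.number}",
            f"initialstate:{self.initialstate}",
            f"seed:{self.seed}",
        ]
        return "\n".join(lines) + "\n"


def _geometry_problems(startage, stopage, interval, number) -> list[str]:
    problems = []
    if not stopage > startage:
        problems.append(f"stopage ({stopage:g}) must exceed startage ({startage:g})")
    if not interval > 0:
        problems.append(f"interval must be positive, got {interval:g}")
    if not number >= 1:
        problems.append(f"number must be at least 1, got {number}")
    if not problems:
        span = stopage - startage
        k = round(span / interval)
        if k < 1 or abs(k * interval - span) > _GRID_TOLERANCE * max(1.0, abs(span)):
            problems.append(
                f"age span {span:g} is not a whole number of intervals of {interval:g}"
            )
    return problems


def parse_config(text: str, model: TransitionModel) -> SimulationConfig:
    """Parse raw config-file content against a parsed model.

    One ``key:value`` pair per non-blank line; whitespace around key and
    value is trimmed, CRLF endings tolerated, ``#`` comment lines
    skipped.  The initial state (given or default) must be a source
    state of the model — a state with no outgoing rules could never
    leave, which is always a specification mistake.
    """
    problems: list[str] = []
    values: dict[str, str] = {}
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\r").strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            problems.append(f"line {line_no}: expected key:value, got {line!r}")
            continue
        key, _, value = line.partition(":")
        key, value = key.strip(), value.strip()
        if key not in _ALL_KEYS:
            problems.append(f"line {line_no}: unknown key {key!r}")
            continue
        if key in values:
            problems.append(f"line {line_no}: duplicate key {key!r}")
            continue
        values[key] = value

    numeric: dict[str, float] = {}
    for key in _NUMERIC_KEYS:
        if key not in values:
            problems.append(f"missing required key {key!r}")
            continue
        try:
            numeric[key] = float(values[key])
        except ValueError:
            problems.append(f"key {key!r}: non-numeric value {values[key]!r}")

    seed: int | str = DEFAULT_SEED
    if "seed" in values:
        if values["seed"].lower() == CLOCK_SEED:
            seed = CLOCK_SEED
        else:
            try:
                seed = int(values["seed"])
            except ValueError:
                problems.append(f"key 'seed': expected a non-negative integer or 'clock', got {values['seed']!r}")
            else:
                if seed < 0:
                    problems.append(f"key 'seed': must be non-negative, got {seed}")

    initialstate = values.get("initialstate", DEFAULT_INITIAL_STATE)
    if not problems and initialstate not in model.source_states:
        problems.append(
            f"initial state {initialstate!r} is not a source state of the model "
            f"(source states: {', '.join(model.source_states)})"
        )

    number = 0
    if "number" in numeric:
        if numeric["number"] != int(numeric["number"]):
            problems.append(f"key 'number': expected an integer, got {values['number']!r}")
        else:
            number = int(numeric["number"])

    if not problems:
        problems = _geometry_problems(numeric["startage"], numeric["stopage"], numeric["interval"], number)
    if problems:
        raise ConfigError(problems)

    return SimulationConfig(
        startage=numeric["startage"],
        stopage=numeric["stopage"],
        interval=numeric["interval"],
        number=number,
        initialstate=initialstate,
        seed=seed,
    )


def load_config(path, model: TransitionModel) -> SimulationConfig:
    with open(path, encoding="utf-8") as fh:
        return parse_config(fh.read(), model)


def recorded_ages(config: SimulationConfig) -> list[float]:
    """The ages at which state is recorded: startage, startage+interval,
    ..., stopage inclusive."""
    return [config.startage + k * config.interval for k in range(config.n_steps + 1)]
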