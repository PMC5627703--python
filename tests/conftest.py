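from pathlib import Path

import pytest

from statesim import SimulationConfig, load_stt

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def example_model():
    """The five-rule cervical-screening-style example model."""
    return load_stt(DATA / "example.stt.txt")


@pytest.fixture(scope="session")
def example_stt_path():
    return DATA / "example.stt.txt"


@pytest.fixture(scope="session")
def example_config_path():
    return DATA / "example.config.txt"


@pytest.fixture(scope="session")
def twostate_model():
    """Single rule normal -> cin1 with per-step probability 0.5."""
    return load_stt(DATA / "twostate.stt.txt")


@pytest.fixture
def twostate_config():
    return SimulationConfig(startage=20, stopage=21, interval=1, number=1000)
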