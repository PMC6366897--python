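import numpy as np
import pytest

from netrig.control import ArenaConfig, GazeWindows, TrialConfig
from netrig.protocol import EventRegistry
from netrig.stimulus import FrameSchedule


@pytest.fixture(scope="session")
def sched():
    return FrameSchedule()


@pytest.fixture(scope="session")
def registry():
    return EventRegistry()


@pytest.fixture
def windows():
    return GazeWindows()


@pytest.fixture
def trial_cfg():
    return TrialConfig()


@pytest.fixture
def arena():
    return ArenaConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
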