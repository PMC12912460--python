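import logging

import numpy as np
import pytest

from hragree.protocol import (
    MIST,
    REST,
    WALKING,
    WALKING_INTERMITTENT,
    Climate,
    ProtocolSpec,
    Task,
)
from hragree.simulate import DeviceErrorModel, RegularSampling, SubjectParams, generate_true_hr

# degenerate single-subject / boundary fits are exercised deliberately; keep
# the expected warnings out of the test output
logging.getLogger("hragree").setLevel(logging.ERROR)

ZERO_CLIMATE = {"neutral": 0.0, "hot": 0.0, "cold": 0.0}


@pytest.fixture(scope="session")
def mini_protocol() -> ProtocolSpec:
    """Short 4-task protocol (6 min per climate) for fast simulations."""
    tasks = (
        Task(REST, 120.0),
        Task(MIST, 60.0),
        Task(WALKING, 60.0),
        Task(WALKING_INTERMITTENT, 120.0),
    )
    return ProtocolSpec(tasks=tasks)


@pytest.fixture(scope="session")
def tiny_protocol() -> ProtocolSpec:
    """Single short rest task per climate, for identifiability checks."""
    return ProtocolSpec(tasks=(Task(REST, 20.0),))


@pytest.fixture
def quiet_subject() -> SubjectParams:
    """Deterministic subject: no physiological noise, no climate effect."""
    return SubjectParams(noise_sd=0.0, climate_increments=dict(ZERO_CLIMATE))


@pytest.fixture
def truth_mini(mini_protocol, quiet_subject):
    return generate_true_hr(quiet_subject, mini_protocol, mini_protocol.climate_labels, seed=11)


@pytest.fixture
def exact_device() -> DeviceErrorModel:
    """Noise-free 1 Hz device: reproduces the truth exactly."""
    return DeviceErrorModel(label="exact", sampling=RegularSampling(1.0))
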