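import numpy as np
import pytest

from accelcal.config import RunConfig
from accelcal.pipeline import PipelineResult, run_endtoend
from accelcal.protocol import default_protocol


@pytest.fixture(scope="session")
def default_cfg() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def default_result(default_cfg) -> PipelineResult:
    """One full default study (30 children, 4 locations), simulated once."""
    return run_endtoend(default_cfg)


@pytest.fixture(scope="session")
def default_protocol_spec(default_cfg):
    return default_protocol(default_cfg)


@pytest.fixture()
def tiny_cfg() -> RunConfig:
    """Scaled-down study for I/O and CLI round trips: short bouts, low rate."""
    return RunConfig(
        n_participants=2,
        sampling_rate_hz=20.0,
        bout_duration_s=150.0,
        rest_duration_s=30.0,
        trim_s=30.0,
        master_seed=99,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
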