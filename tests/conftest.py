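import numpy as np
import pytest

from sprstress.simulate import SimConfig, gen_recording


@pytest.fixture(scope="session")
def short_cfg() -> SimConfig:
    """2-minute study-condition recording config for fast stage tests."""
    return SimConfig(duration_s=120.0, seed=7)


@pytest.fixture(scope="session")
def traffic_recording(short_cfg):
    return gen_recording(short_cfg, scenario="traffic", subject_id="S01")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
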