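import numpy as np
import pytest

from frproi.headmodel import standard_head
from frproi.simulate import SimConfig, simulate_session


@pytest.fixture(scope="session")
def head():
    return standard_head()


@pytest.fixture(scope="session")
def small_session():
    """A 150-fixation session shared by the cheaper integration tests."""
    return simulate_session(SimConfig(events_per_condition=30), seed=7)


@pytest.fixture(scope="session")
def analyzed_small(small_session):
    """The shared session run through the full pipeline once."""
    from frproi.pipeline import PipelineConfig, analyze_session

    return analyze_session(small_session, PipelineConfig(ica_components=16),
                           seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
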