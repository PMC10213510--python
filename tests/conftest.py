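import numpy as np
import pytest

from rhythmgap import ExperimentConfig, ObserverProfile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def config():
    return ExperimentConfig()


@pytest.fixture
def young_observer():
    return ObserverProfile(group="young")


@pytest.fixture
def lapse_free_observer():
    return ObserverProfile(group="young", lapse=0.0)
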