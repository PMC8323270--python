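import numpy as np
import pytest

from seiznet import default_montage, default_seizure_schedule, simulate


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def schedule():
    return default_seizure_schedule()


@pytest.fixture(scope="session")
def recording(schedule):
    """One default surrogate recording, shared across tests."""
    return simulate(schedule, seed=12345)


@pytest.fixture(scope="session")
def pipeline_result(recording):
    from seiznet import run_pipeline
    return run_pipeline(recording)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
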