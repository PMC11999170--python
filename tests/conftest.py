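import numpy as np
import pandas as pd
import pytest

from cgmforecast.data import GlucoseTrace, SubjectRecord
from cgmforecast.network import ArchitectureSpec, TrainConfig
from cgmforecast.simulate import SimConfig, simulate_subject

START = pd.Timestamp("2021-01-04T00:00:00")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trace(values, subject_id="t", start=START, flags=None):
    return GlucoseTrace(subject_id, start, np.asarray(values, dtype=float), flags)


@pytest.fixture
def constant_trace():
    """One gapless day at 120 mg/dL."""
    return make_trace(np.full(288, 120.0))


@pytest.fixture(scope="session")
def sim_subject_10wk():
    """A stationary 70-day synthetic subject shared by training tests."""
    return simulate_subject(SimConfig(n_days=70, seed=5))


@pytest.fixture(scope="session")
def tiny_arch():
    """Reduced network size used by training tests to keep runtimes short."""
    return ArchitectureSpec(layer1_units=16, layer2_units=8)


@pytest.fixture(scope="session")
def fast_train():
    """Short per-block epoch budget for quick-turnaround unit tests."""
    return TrainConfig(max_epochs=8, patience=3)
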