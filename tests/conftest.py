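import numpy as np
import pytest

from corticograph import GeneratorProfile, generate_trial
from corticograph.pipeline import trial_to_graphs
from corticograph.preprocessing import preprocess_trial


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_profile():
    return GeneratorProfile.default()


@pytest.fixture(scope="session")
def sample_trial(default_profile):
    return generate_trial("push", default_profile, seed=7)


@pytest.fixture(scope="session")
def sample_segments(sample_trial):
    return preprocess_trial(sample_trial)


@pytest.fixture(scope="session")
def sample_segment(sample_segments):
    return sample_segments[0]


@pytest.fixture(scope="session")
def sample_graphs(sample_trial):
    """Six graphs of one preprocessed push trial (built once per session)."""
    return trial_to_graphs(sample_trial)
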