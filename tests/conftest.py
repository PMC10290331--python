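import numpy as np
import pytest

from kinemg.protocols import pairs_from_recordings
from kinemg.synth import ProtocolConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    """A desk-scale session: 2 subjects x 3 tasks x 3 repetitions."""
    return ProtocolConfig(n_subjects=2, n_tasks=3, n_repetitions=3, seed=11)


@pytest.fixture(scope="session")
def small_recordings(small_config):
    recordings, _ = generate_dataset(small_config)
    return recordings


@pytest.fixture(scope="session")
def small_pairs(small_recordings):
    """Un-normalized sequence pairs of the desk-scale session."""
    return pairs_from_recordings(small_recordings)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
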