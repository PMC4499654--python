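import numpy as np
import pytest

from ecgdx.bp_core import TrainingConfig
from ecgdx.classifiers import build_pattern_library, train_pattern_net


@pytest.fixture(scope="session")
def pattern_library():
    return build_pattern_library()


@pytest.fixture(scope="session")
def trained_pattern_net(pattern_library):
    """A 10-10-8 net trained on the reference patterns to E < 0.1 (shared)."""
    net, report = train_pattern_net(TrainingConfig(rng_seed=1), pattern_library)
    assert report.converged, "reference-pattern training did not converge"
    return net


@pytest.fixture
def rng():
    return np.random.default_rng(42)
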