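import numpy as np
import pytest

from cortexnet import (
    CorticalModule,
    NetworkParams,
    make_orthogonal_patterns,
    make_shifted_patterns,
)


@pytest.fixture(scope="session")
def forward_set():
    """The standard 28 shifted forward patterns (20 of 100 active, offset 3)."""
    return make_shifted_patterns(28, 100, 20, 3)


@pytest.fixture(scope="session")
def backproj_set():
    """The standard 28 disjoint backprojection cues (3 of 100 active)."""
    return make_orthogonal_patterns(28, 100, 3)


@pytest.fixture(scope="session")
def default_params():
    return NetworkParams()


@pytest.fixture(scope="session")
def fitted(forward_set, backproj_set, default_params):
    """One default trained module, shared across read-only tests."""
    return CorticalModule(forward_set, backproj_set, default_params).fit(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
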