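import numpy as np
import pytest

from dmdrex.models import GoParameterSet, build_mini_bundle
from dmdrex.topology import mini_bundle_topology


@pytest.fixture(scope="session")
def mini_topology():
    return mini_bundle_topology()


@pytest.fixture(scope="session")
def mini_bundle(mini_topology):
    """Default 56-bead idealized bundle: (model, state); do not mutate."""
    return build_mini_bundle(mini_topology, GoParameterSet(), seed=1)


@pytest.fixture()
def thermal_state(mini_bundle):
    _, state = mini_bundle
    st = state.copy()
    st.thermalize(0.5, np.random.default_rng(7))
    return st
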