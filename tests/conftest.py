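import numpy as np
import pytest

import bciloop as b


@pytest.fixture(scope="session")
def alternating_intent():
    """Square-wave session: 6 movement epochs of 5 s separated by rest."""
    protocol = [("attempt_close", 5.0), ("rest", 5.0)] * 6
    return b.make_intent_trace(protocol, seed=7)


@pytest.fixture(scope="session")
def small_neural_cfg():
    return b.NeuralSimConfig(n_channels=8, n_active_channels=4, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
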