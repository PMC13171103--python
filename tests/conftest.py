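import numpy as np
import pytest

from setshift import GeneratorConfig, generate_session, label_states


@pytest.fixture(scope="session")
def control_session():
    """One deterministic control session at default desk scale."""
    return generate_session(GeneratorConfig.preset("control"), 1234)


@pytest.fixture(scope="session")
def control_labeling(control_session):
    return label_states(control_session.trials)


@pytest.fixture(scope="session")
def small_session():
    """Small, fast session with a fixed switch point for decoder tests."""
    cfg = GeneratorConfig.preset(
        "control", n_neurons=40, switch_trial=("fixed", 12)
    )
    return generate_session(cfg, 99)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
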