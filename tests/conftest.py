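import numpy as np
import pytest

import ringsim as rs


@pytest.fixture
def rng():
    return np.random.default_rng(1)


@pytest.fixture(scope="session")
def protos():
    """Noise-free prototype set shared across tests (deterministic)."""
    return rs.make_prototypes(4, 64, 0.0, 1)


@pytest.fixture
def named_model_b(protos, rng):
    """Model B whose perception layer has been through the naming stage
    for stimulus B (index 1), five supervised steps."""
    model = rs.make_model_b(4, 64)
    for _ in range(5):
        model.layer = rs.learn_label(model.layer, rs.observe(protos[1], rng), 1)
    return model


@pytest.fixture
def named_model_a(protos, rng):
    """Model A named on stimulus B (one supervised step, then readout
    calibration)."""
    model = rs.make_model_a(4, 64)
    model.layer = rs.learn_label(model.layer, rs.observe(protos[1], rng), 1)
    model.layer = rs.calibrate_theta_h(model.layer, [protos[1]])
    return model
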