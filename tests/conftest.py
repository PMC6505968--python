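import numpy as np
import pytest
from hypothesis import settings

from brainabc.models import get_model

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from brainabc.protocols import ProtocolSpec, gen_hypoxia_protocol


@pytest.fixture(scope="session")
def minibrain():
    return get_model("minibrain")


@pytest.fixture(scope="session")
def toy():
    return get_model("toy")


@pytest.fixture(scope="session")
def healthy_protocol():
    """Simulated healthy hypoxia challenge: (inputs, outputs)."""
    return gen_hypoxia_protocol(ProtocolSpec(state="healthy"))


@pytest.fixture(scope="session")
def impaired_protocol():
    """Same inputs, vessel-stiffened (r_t = 0.013 cm) model."""
    return gen_hypoxia_protocol(ProtocolSpec(state="impaired"))


@pytest.fixture(scope="session")
def baseline_inputs():
    return {"ABP": 100.0, "SaO2": 97.0, "PaCO2": 40.0}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
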