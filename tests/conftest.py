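import numpy as np
import pytest

from genarith.config import RunConfig
from genarith.genotype_arithmetic import predict_binding_sites


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def n7_report():
    """Default deterministic n=7 prediction, shared across tests."""
    return predict_binding_sites(7, RunConfig(n=7, seed=42))
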