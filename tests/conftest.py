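import numpy as np
import pytest
from hypothesis import settings

import turingtransients as tt

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=25)
settings.load_profile("ci")

MODEL_IDS = tt.models.MODEL_IDS


@pytest.fixture(scope="session")
def base_specs():
    return {mid: tt.base_model(mid) for mid in MODEL_IDS}


@pytest.fixture(scope="session")
def base_equilibria(base_specs):
    return {mid: tt.find_equilibria(spec) for mid, spec in base_specs.items()}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)
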