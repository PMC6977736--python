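import numpy as np
import pytest
from hypothesis import settings

# deterministic hypothesis runs
settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)
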