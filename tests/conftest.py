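import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from cafswitch import ScenarioPreset, generate_truth

hypothesis_settings.register_profile("deterministic", derandomize=True, deadline=None)
hypothesis_settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_truth():
    """Ground-truth trajectory of the packaged default scenario (0-72 h)."""
    return generate_truth(ScenarioPreset())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
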