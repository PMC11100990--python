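import numpy as np
import pytest

from ginger.ibl import AgentParams
from ginger.representations import BVAESpec, render_stimulus
from ginger.runner import StimulusRepresenter, all_stimulus_specs


@pytest.fixture
def quiet_params():
    """Default IBL parameters with activation noise disabled."""
    return AgentParams(noise_on=False)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def trained_representer():
    """One beta-VAE trained on the full stimulus set, shared across tests
    (training is the expensive step; encoding is cached)."""
    return StimulusRepresenter(BVAESpec(seed=202))


@pytest.fixture(scope="session")
def stimulus_images():
    return [render_stimulus(s) for s in all_stimulus_specs()]
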