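import pytest
from hypothesis import settings

from phytoshelf import StudyDesign, generate, noise_free

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noise_free_samples():
    """Default design with the noise switched off: means are exact."""
    return generate(noise_free(StudyDesign(seed=7)))


@pytest.fixture(scope="session")
def noisy_samples():
    """Default design at the calibrated noise level."""
    return generate(StudyDesign(seed=7))
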