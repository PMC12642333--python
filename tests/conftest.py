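import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def synth_truth():
    from agesim.io_synth import DEFAULT_SYNTH_PARAMS

    return DEFAULT_SYNTH_PARAMS


@pytest.fixture
def noiseless_table(synth_truth):
    from agesim.io_synth import SynthSpec, synth_mortality

    return synth_mortality(SynthSpec(params=synth_truth, noise_sd=0.0))


@pytest.fixture
def noisy_table(synth_truth):
    from agesim.io_synth import SynthSpec, synth_mortality

    return synth_mortality(SynthSpec(params=synth_truth, noise_sd=0.05, seed=1))
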