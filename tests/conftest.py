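import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def small_separable_dataset():
    """A compact, strongly separated two-class sequence dataset."""
    from thermoseq.synth import SynthConfig, generate

    return generate(
        SynthConfig(
            n_pos=60, n_neg=60, length_range=(40, 120), effect_size=0.9, seed=11
        )
    )
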