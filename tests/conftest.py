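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
    return np.random.default_rng(1234)


@pytest.fixture
def small_streams():
    """Small multi-position dataset for pipeline-level tests."""
    from harfuse.synthdata import SynthConfig, generate_dataset

    cfg = SynthConfig(
        n_subjects=1,
        n_positions=3,
        activities=("walking", "sitting", "lying"),
        duration_per_activity=12.0,
        separability=(2.0, 1.5, 1.0),
        noise_sd=0.5,
        seed=7,
    )
    return generate_dataset(cfg)
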