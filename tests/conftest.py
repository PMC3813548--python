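import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def small_recording(rng):
    """A 30 s, 4-channel artifact-free recording with known correlations."""
    from seegconn import ArtifactSpec, sample_target_correlation, simulate_recording

    target = sample_target_correlation(4, 0.3, 0.05, rng)
    return simulate_recording(
        target,
        sampling_rate=200.0,
        duration=30.0,
        artifacts=ArtifactSpec.none(),
        region_labels=["HH", "A", "STG", "TP"],
        rng=rng,
        patient_id="T01",
        outcome=True,
    )
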