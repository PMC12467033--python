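import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def registry():
    from enzybind import default_registry

    return default_registry()


@pytest.fixture
def mixed_truth():
    """Mixed-inhibition ground truth with the apparent-constant scale of a
    typical porphyrin/amylase system."""
    from enzybind import GroundTruth

    return GroundTruth(
        stage="kinetics",
        parameters={
            "inhibition_type": "mixed",
            "km": 3.9047,
            "vmax": 0.1826,
            "ki": 8.7057,
            "kis": 21.2847,
        },
    )
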