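import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_study():
    from teatrace.datasets import load_reference_study
    return load_reference_study()


@pytest.fixture(scope="session")
def soil_summary():
    from teatrace.datasets import load_soil_summary
    return load_soil_summary()


@pytest.fixture(scope="session")
def infusion_summary():
    from teatrace.datasets import load_infusion_summary
    return load_infusion_summary()


@pytest.fixture(scope="session")
def synth_default():
    """One default-condition synthetic study with its ground truth."""
    from teatrace.synthetic import GeneratorConfig, simulate_study
    return simulate_study(GeneratorConfig(seed=42))
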