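import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def baseline_inputs():
    from pdacpath import load_config

    return load_config()


@pytest.fixture(scope="session")
def baseline_model():
    from pdacpath import PathwayDecisionModel

    return PathwayDecisionModel.from_config()


@pytest.fixture(scope="session")
def baseline_results(baseline_model):
    return baseline_model.fit()
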