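from importlib import resources

import pytest
from hypothesis import HealthCheck, settings

from orphanmcda import builtin_scenarios, default_framework
from orphanmcda.io import read_profiles

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def framework():
    return default_framework()


@pytest.fixture(scope="session")
def scenarios():
    return builtin_scenarios()


@pytest.fixture(scope="session")
def example_profiles(framework):
    """The packaged illustrative six-drug cohort (synthetic values)."""
    path = resources.files("orphanmcda.data").joinpath("example_cohort_synthetic.csv")
    with resources.as_file(path) as p:
        return read_profiles(p, framework)
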