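import pytest
from hypothesis import HealthCheck, settings

from cortstress import default_study_config, simulate_dataset

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_ds():
    """One dataset drawn under the study's default sampling design."""
    return simulate_dataset(default_study_config())
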