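import pytest
from hypothesis import HealthCheck, settings

from star_cea import builtin_star_parameters

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture()
def base_params():
    """A fresh copy of the built-in base-case parameter bundle."""
    return builtin_star_parameters()
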