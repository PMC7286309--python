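import logging

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

logging.getLogger("gbkit").setLevel(logging.WARNING)


@pytest.fixture
def tiny_tree() -> str:
    return "(A:0.3,(B:0.2,C:0.2)N1:0.1)root;"
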