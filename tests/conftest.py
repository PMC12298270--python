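import pytest
from hypothesis import HealthCheck, settings

from caftorlab import default_panel

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def iva(panel):
    return panel.get("IVA")
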