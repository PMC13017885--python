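import pytest

from wheatgdt import default_config


@pytest.fixture
def config():
    """Default reference scenario, short horizon for speed."""
    return default_config(horizon_days=40, seed=7)


@pytest.fixture
def full_config():
    """Full-season reference scenario."""
    return default_config(horizon_days=150, seed=7)
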