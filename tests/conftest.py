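import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def bulk_chain():
    """Medium-length bulk-regime chain shared across unit tests."""
    from csarpipe import fixtures, gen_rotamer_chain

    return gen_rotamer_chain(fixtures.bulk_regime_spec(), 200_000, fixtures.BULK_DT, seed=11)


@pytest.fixture(scope="session")
def surface_chain():
    """Medium-length surface-regime chain shared across unit tests."""
    from csarpipe import fixtures, gen_rotamer_chain

    return gen_rotamer_chain(
        fixtures.surface_regime_spec(), 200_000, fixtures.SURFACE_DT, seed=12
    )

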