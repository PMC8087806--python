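import numpy as np
import pytest

from edisle import (
    default_amplicon,
    default_control_distribution,
    simulate_reads,
)


@pytest.fixture(scope="session")
def ref():
    return default_amplicon()


@pytest.fixture(scope="session")
def control_dist():
    return default_control_distribution()


@pytest.fixture(scope="session")
def control_reads_50k(ref, control_dist):
    """One deep error-free replicate of the default control profile."""
    return simulate_reads(control_dist, ref, depth=50_000, error_rate=0.0, seed=101)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
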