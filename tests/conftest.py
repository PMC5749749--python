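import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from localsw import make_dna_scheme  # noqa: E402


@pytest.fixture(scope="session")
def dna_scheme():
    """Default DNA scheme: match 5, mismatch -4, gap open 10, basic mode."""
    return make_dna_scheme()


@pytest.fixture(scope="session", autouse=True)
def warm_kernels(dna_scheme):
    """Trigger kernel JIT compilation once, outside any timed assertion."""
    from localsw import align_pair, make_dna_scheme

    align_pair("ACGT", "ACGT", dna_scheme)
    align_pair("ACGT", "ACGT", make_dna_scheme(5, -4, 4, 1))


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_901)
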