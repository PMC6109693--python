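import pytest
from hypothesis import settings

from mgspipe import synthio

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def truth():
    """Default synthetic community, shared across the suite."""
    return synthio.gen_truth_set(seed=7)


@pytest.fixture(scope="session")
def sim(truth):
    """Simulated reads + truth alignments for the default community."""
    return synthio.simulate_reads(truth)
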