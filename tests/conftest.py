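import pytest

from dazfam import pipeline
from dazfam.simulate import make_benchmark


@pytest.fixture(scope="session")
def bench():
    """Default synthetic benchmark, fixed seed shared across the suite."""
    return make_benchmark("default", seed=1)


@pytest.fixture(scope="session")
def bundle(bench):
    """Signatures/profiles derived from the benchmark training leaves."""
    return pipeline.derive_signatures(bench)
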