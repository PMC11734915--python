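import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_read(read_id, positions, states, sample_id="s1", chrom="chr1",
              start=None, end=None):
    """Convenience constructor used across test modules."""
    from imprintscreen import ReadMethCall

    positions = list(positions)
    if start is None:
        start = min(positions) if positions else 0
    if end is None:
        end = (max(positions) + 1) if positions else start + 100
    return ReadMethCall(
        read_id=read_id,
        sample_id=sample_id,
        chrom=chrom,
        start=start,
        end=end,
        cpg_calls=tuple(zip(positions, states)),
    )


@pytest.fixture
def read_factory():
    return make_read
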