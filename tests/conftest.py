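import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20259)


@pytest.fixture
def toy_peaks():
    from c4map.formats import GenomicInterval, PeakSet

    return PeakSet(
        "toy",
        [
            GenomicInterval("chr1", 10, 20, "+", "a", 1.5),
            GenomicInterval("chr1", 40, 80, "-", "b"),
            GenomicInterval("chr2", 0, 5, ".", "c"),
        ],
    )
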