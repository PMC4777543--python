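import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from targetome.intervals import GenomicInterval, Peak, PeakSet

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_peakset(rng: np.random.Generator, n: int, n_chroms: int = 2,
                   span: int = 10_000, max_width: int = 60, prefix: str = "p") -> PeakSet:
    """Dense random peaks on a short genome, guaranteed to produce overlaps."""
    peaks = []
    for i in range(n):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, span))
        width = int(rng.integers(1, max_width))
        peaks.append(Peak(GenomicInterval(chrom, start, start + width),
                          float(rng.integers(0, 500)), name=f"{prefix}{i}"))
    return PeakSet(peaks)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
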