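import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chipnorm.io_binning import BinnedLibrary, GenomeLayout

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_layout() -> GenomeLayout:
    """Two small chromosomes, 1 kb bins (12 + 8 bins)."""
    return GenomeLayout((("chr1", 12_000), ("chr2", 8_000)), 1000)


@pytest.fixture
def one_chrom_layout() -> GenomeLayout:
    return GenomeLayout((("chr1", 100_000),), 1000)


def make_library(layout: GenomeLayout, counts) -> BinnedLibrary:
    return BinnedLibrary(layout, np.asarray(counts, dtype=np.int64))
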