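import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from scnakit.genome import make_bins, scaled_autosomes


@pytest.fixture(scope="session")
def small_bins():
    """10 equal 1 Mb bins on one chromosome."""
    return make_bins({"chr1": 10_000_000}, 1_000_000)


@pytest.fixture(scope="session")
def two_chrom_bins():
    """Two chromosomes, 5 + 3 bins."""
    return make_bins({"chr1": 5_000_000, "chr2": 3_000_000}, 1_000_000)


@pytest.fixture(scope="session")
def genome_bins():
    """Scaled 22-autosome genome with 5 Mb bins (default analysis grid)."""
    return make_bins(scaled_autosomes(), 5_000_000)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
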