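import numpy as np
import pytest

from seqmm import ContactMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_cm(rng):
    """Random symmetric nonnegative 12x12 contact matrix."""
    a = rng.uniform(0, 10, size=(12, 12))
    return ContactMatrix(a + a.T, bin_size=100_000, chrom="chrR")


@pytest.fixture
def two_block_cm():
    """Noise-free 40-bin matrix of two 20-bin blocks with no cross contact."""
    n = 40
    m = np.zeros((n, n))
    m[:20, :20] = 8.0
    m[20:, 20:] = 8.0
    np.fill_diagonal(m, 10.0)
    return ContactMatrix(m, bin_size=100_000, chrom="chrT")
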