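import numpy as np
import pytest

from loopscape import ContactMatrix, GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def symmetric_random_matrix(rng, n, scale=10.0):
    a = rng.uniform(0, scale, size=(n, n))
    return 0.5 * (a + a.T)


@pytest.fixture
def random_matrix(rng):
    def make(n=20, bin_size=10_000, scale=10.0, chrom="chrT"):
        return ContactMatrix(chrom, bin_size, symmetric_random_matrix(rng, n, scale))

    return make


def interval(start, end, chrom="chrT", strand="."):
    return GenomicInterval(chrom, start, end, strand)
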