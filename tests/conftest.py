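import numpy as np
import pytest

from hicenhance import ContactMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_symmetric_counts(rng, n, lam=4.0, chrom="chrT", resolution=10_000):
    """Symmetric integer count matrix with Poisson-ish entries."""
    upper = rng.poisson(lam, size=(n, n))
    sym = np.triu(upper) + np.triu(upper, k=1).T
    return ContactMatrix(chrom, resolution, sym.astype(float))


@pytest.fixture
def small_counts(rng):
    return random_symmetric_counts(rng, 12)
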