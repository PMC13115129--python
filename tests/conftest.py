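import numpy as np
import pytest

from egscreen.io import GenotypeMatrix, LocusMeta


def make_matrix(calls, samples=None, chrom="1"):
    """GenotypeMatrix from a nested list of codes (-1/0/1/2)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    samples = samples or [f"s{i}" for i in range(n)]
    loci = [LocusMeta(chrom=chrom, pos=j + 1, id=f"L{j}") for j in range(m)]
    return GenotypeMatrix(samples=samples, loci=loci, calls=calls)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_matrix(rng):
    """5 x 20 matrix with all four call states present."""
    calls = rng.choice([-1, 0, 1, 2], size=(5, 20), p=[0.1, 0.3, 0.3, 0.3])
    return make_matrix(calls)
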