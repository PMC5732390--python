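import numpy as np
import pytest

from grsxe.core import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_genotypes(dosages, snp_ids=None, **kw) -> GenotypeMatrix:
    d = np.asarray(dosages, dtype=np.int8)
    n, k = d.shape
    return GenotypeMatrix(
        dosages=d,
        sample_ids=[f"s{i}" for i in range(n)],
        snp_ids=snp_ids or [f"snp{j}" for j in range(k)],
        **kw,
    )


@pytest.fixture
def small_genotypes(rng) -> GenotypeMatrix:
    return make_genotypes(rng.binomial(2, 0.3, size=(50, 4)))
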