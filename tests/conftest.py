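import numpy as np
import pandas as pd
import pytest

from cislmm.lmm import GenotypeMatrix


def make_genotype_matrix(dosages: np.ndarray, chrom: str = "1", positions=None) -> GenotypeMatrix:
    """Wrap a raw dosage array with minimal variant/sample metadata."""
    n, p = dosages.shape
    if positions is None:
        positions = np.arange(1, p + 1) * 1000
    variants = pd.DataFrame(
        {
            "id": [f"v{j}" for j in range(p)],
            "chrom": chrom,
            "pos": positions,
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix(
        samples=[f"S{i}" for i in range(n)], variants=variants, dosages=dosages
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240904)


@pytest.fixture
def small_geno(rng):
    """20 samples x 5 SNPs of HWE-ish dosages."""
    from cislmm.simulate import simulate_genotypes

    return simulate_genotypes(20, 5, seed=11)


@pytest.fixture
def medium_geno():
    from cislmm.simulate import simulate_genotypes

    return simulate_genotypes(60, 10, seed=13)
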