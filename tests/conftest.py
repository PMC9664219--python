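import numpy as np
import pytest

from epiblup.io import GenotypeMatrix, PhenotypeTable


@pytest.fixture
def tiny_genotypes() -> GenotypeMatrix:
    """3 individuals x 2 SNPs, codes chosen to cover 0/1/2."""
    return GenotypeMatrix(
        codes=np.array([[0, 2], [1, 1], [2, 0]]),
        sample_ids=np.array(["a", "b", "c"]),
        snp_ids=np.array(["s1", "s2"]),
        chromosome=np.array([1, 2]),
    )


@pytest.fixture
def random_genotypes() -> GenotypeMatrix:
    """Seeded 8-individual x 10-SNP panel on two chromosomes."""
    rng = np.random.default_rng(42)
    p = rng.uniform(0.2, 0.8, 10)
    return GenotypeMatrix(
        codes=rng.binomial(2, p, size=(8, 10)),
        sample_ids=np.array([f"i{k}" for k in range(8)]),
        snp_ids=np.array([f"s{k}" for k in range(10)]),
        chromosome=np.repeat([1, 2], 5),
    )


@pytest.fixture
def pheno_n100() -> PhenotypeTable:
    rng = np.random.default_rng(0)
    y = rng.standard_normal(100)
    return PhenotypeTable(np.array([f"i{k}" for k in range(100)]), y)
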