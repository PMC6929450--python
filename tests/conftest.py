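import numpy as np
import pytest

from targetsnp import GenotypeMatrix


def make_matrix(codes, samples=None, loci=None):
    codes = np.asarray(codes, dtype=np.int8)
    samples = samples or [f"s{i + 1}" for i in range(codes.shape[0])]
    loci = loci or [f"snp{j + 1}" for j in range(codes.shape[1])]
    return GenotypeMatrix(samples, loci, codes)


@pytest.fixture
def tiny_matrix():
    """3 samples x 2 SNPs used in the worked selection example."""
    return make_matrix([[0, 0], [0, 1], [1, 1]], loci=["SNP1", "SNP2"])


@pytest.fixture
def structured():
    """Two clearly diverged populations of 20 samples, 30 loci."""
    from targetsnp import simulate_structured_genotypes

    gm, truth = simulate_structured_genotypes(
        sizes=(20, 20), n_loci=30, fst_star=0.3, seed=11
    )
    return gm, truth
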