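import numpy as np
import pytest

from cdiadem import genotypes as G
from cdiadem import pathways as P
from cdiadem import simulate


def random_genotype_matrix(rng: np.random.Generator, n_samples: int, n_snps: int,
                           missing_rate: float = 0.0) -> G.GenotypeMatrix:
    codes = rng.integers(0, 3, size=(n_samples, n_snps)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(codes.shape) < missing_rate
        codes[mask] = G.MISSING
    alleles = np.array(list("ACGT"))
    variants = []
    for j in range(n_snps):
        a, b = rng.choice(4, size=2, replace=False)
        variants.append(G.VariantRecord(
            snp_id=f"rs{j:05d}", chrom=str(1 + j % 3), pos=100 + 10 * j,
            allele_minor=str(alleles[a]), allele_major=str(alleles[b]),
        ))
    samples = [f"S{i:03d}" for i in range(n_samples)]
    return G.GenotypeMatrix(samples=samples, variants=variants, codes=codes)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The packaged miniature cohort, written once per session."""
    d = tmp_path_factory.mktemp("fixture")
    simulate.small_fixture(out_dir=d)
    return d


@pytest.fixture(scope="session")
def fixture_cohort(fixture_dir):
    return simulate.small_fixture()


@pytest.fixture(scope="session")
def fixture_collection(fixture_cohort):
    return P.GeneSetCollection(
        [P.GeneSet(n, d, tuple(m)) for n, d, m in fixture_cohort.gene_sets]
    )
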