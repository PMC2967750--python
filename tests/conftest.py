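import numpy as np
import pytest

from phapscore.genotype_io import GeneInterval, GenotypeMatrix, VariantRecord


def make_matrix(dosages, chrom="chr1", start_pos=100, spacing=1000, sample_prefix="s",
                variant_ids=None, chroms=None):
    """Build a GenotypeMatrix from a 2-D array (NaN = missing)."""
    dosages = np.asarray(dosages, dtype=float)
    n, v = dosages.shape
    if variant_ids is None:
        variant_ids = [f"rs{j + 1}" for j in range(v)]
    if chroms is None:
        chroms = [chrom] * v
    variants = [
        VariantRecord(variant_ids[j], chroms[j], start_pos + j * spacing, "A", "G")
        for j in range(v)
    ]
    samples = [f"{sample_prefix}{i + 1}" for i in range(n)]
    return GenotypeMatrix(sample_ids=samples, variants=variants, dosages=dosages)


def random_matrix(rng, n_samples, n_variants, missing_rate=0.0, chrom="chr1"):
    d = rng.integers(0, 3, size=(n_samples, n_variants)).astype(float)
    if missing_rate:
        d[rng.random(d.shape) < missing_rate] = np.nan
    return make_matrix(d, chrom=chrom)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gene_10k():
    return GeneInterval("GENE1", "chr1", 10000, 20000)
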