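import numpy as np
import pandas as pd
import pytest

from mscomorb.genotype_qc import GenotypeMatrix


def make_matrix(dosages, r2=None, chrom=None, sample_ids=None, reported_sex=None):
    """Assemble a GenotypeMatrix from a raw dosage array with default metadata."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": np.arange(100, 100 + m),
            "ref": ["A"] * m,
            "alt": ["G"] * m,
            "r2": r2 if r2 is not None else [1.0] * m,
            "is_hla": [False] * m,
        }
    )
    samples = pd.DataFrame(
        {"sample_id": sample_ids if sample_ids is not None else [f"s{i}" for i in range(n)]}
    )
    if reported_sex is not None:
        samples["reported_sex"] = reported_sex
    return GenotypeMatrix(dosages=dosages, variants=variants, samples=samples)


def permuted_genotype_rows(n_samples, counts=(15, 30, 15), seed=0):
    """Rows with identical genotype multisets (hom-ref, het, hom-alt) permuted.

    Every sample then has exactly the same heterozygosity, which keeps
    SD-based sample filters silent by construction.
    """
    rng = np.random.default_rng(seed)
    base = np.repeat([0.0, 1.0, 2.0], counts)
    return np.stack([rng.permutation(base) for _ in range(n_samples)])


@pytest.fixture
def uniform_het_matrix():
    """Clean 40-sample matrix with identical per-sample heterozygosity."""
    return make_matrix(permuted_genotype_rows(40, seed=11))
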