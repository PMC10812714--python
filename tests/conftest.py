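import numpy as np
import pandas as pd
import pytest

from popgenscan import GenotypeMatrix, PopulationMap, VariantTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240307)


def make_dataset(dosages, chrom="1", positions=None, sample_prefix="s"):
    """Small VariantTable + GenotypeMatrix from a dosage array."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_loci, n_samples = dosages.shape
    if positions is None:
        positions = np.arange(1, n_loci + 1) * 100
    refs = ["A"] * n_loci
    alts = ["G"] * n_loci
    vt = VariantTable(
        pd.DataFrame(
            {
                "chrom": [chrom] * n_loci,
                "pos": positions,
                "id": ".",
                "ref": refs,
                "alt": alts,
                "biallelic_snp": True,
            }
        )
    )
    gm = GenotypeMatrix(dosages, [f"{sample_prefix}{i}" for i in range(n_samples)])
    return vt, gm


def two_pop_map(n_a, n_b, label_a="A", label_b="B", sample_prefix="s"):
    assignments = {}
    for i in range(n_a + n_b):
        assignments[f"{sample_prefix}{i}"] = label_a if i < n_a else label_b
    return PopulationMap(assignments)


@pytest.fixture
def small_two_pop(rng):
    """Random 60-locus, 5+5-sample two-population dataset with missingness."""
    dosages = rng.integers(0, 3, size=(60, 10)).astype(np.int8)
    miss = rng.random((60, 10)) < 0.1
    dosages[miss] = -1
    vt, gm = make_dataset(dosages)
    return vt, gm, two_pop_map(5, 5)
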