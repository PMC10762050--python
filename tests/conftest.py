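import numpy as np
import pandas as pd
import pytest

from hrrscan import GenotypeMatrix, make_sample_table


def make_snpmap(positions, chrom="1", offset=0):
    """Single-chromosome map from a list of bp positions."""
    return pd.DataFrame({
        "snp_id": [f"c{chrom}_s{i + offset}" for i in range(len(positions))],
        "chrom": str(chrom),
        "pos_bp": np.asarray(positions, dtype=np.int64),
        "allele1": "A",
        "allele2": "G",
    })


def evenly_spaced_map(n_snp, spacing=25_000, chrom="1", start=1):
    return make_snpmap([start + i * spacing for i in range(n_snp)], chrom=chrom)


def random_population(rng, n_breeds=3, n_ind=8, n_snp=60, p_het=0.3,
                      p_miss=0.05):
    """Unstructured random genotypes with a breed layout, for unit tests."""
    breeds = [f"B{k}" for k in range(n_breeds) for _ in range(n_ind)]
    ids = [f"B{k}_i{j}" for k in range(n_breeds) for j in range(n_ind)]
    u = rng.random((len(ids), n_snp))
    codes = np.where(u < p_het, 1, np.where(u < p_het + (1 - p_het) / 2, 0, 2))
    codes = codes.astype(np.int8)
    codes[rng.random(codes.shape) < p_miss] = -1
    g = GenotypeMatrix(ids, codes)
    return g, evenly_spaced_map(n_snp), make_sample_table(ids, breeds)


@pytest.fixture
def rng():
    return np.random.default_rng(20231201)


@pytest.fixture
def small_pop(rng):
    return random_population(rng)
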