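import numpy as np
import pandas as pd
import pytest

from saeibs.matrix import GenotypeMatrix
from saeibs.simulate import SimConfig, simulate_populations


def make_variants(m, chrom="1", ref="A", alt="G"):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "id": [f"snp{j + 1}" for j in range(m)],
            "pos": np.arange(1, m + 1) * 1000,
            "ref": ref,
            "alt": alt,
        }
    )


def make_genotypes(values, labels=None):
    values = np.asarray(values, dtype=np.int8)
    n, m = values.shape
    return GenotypeMatrix(
        values=values,
        sample_ids=[f"s{i + 1}" for i in range(n)],
        variants=make_variants(m),
        labels=labels,
    )


def split_reference_target(g, n_ref_per_pop):
    """Stratified split of a labelled fixture into reference and target."""
    lab = np.asarray(g.labels)
    ref_idx, tgt_idx = [], []
    for pop in np.unique(lab):
        members = np.flatnonzero(lab == pop)
        ref_idx += members[:n_ref_per_pop].tolist()
        tgt_idx += members[n_ref_per_pop:].tolist()
    return g.take_samples(ref_idx), g.take_samples(tgt_idx)


@pytest.fixture(scope="session")
def three_pop():
    """3 populations x 100 samples, 1000 SNPs, Fst 0.1."""
    return simulate_populations(
        SimConfig(n_pops=3, n_per_pop=100, m_snps=1000, fst=0.1, seed=42)
    )


@pytest.fixture(scope="session")
def small_pop():
    """Small 2-population fixture for fast unit tests."""
    return simulate_populations(
        SimConfig(n_pops=2, n_per_pop=30, m_snps=200, fst=0.2, seed=7)
    )
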