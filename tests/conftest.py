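import numpy as np
import pandas as pd
import pytest

import milknet as mk


@pytest.fixture(scope="session")
def small_config() -> mk.SimConfig:
    """A 150-cow, 400-SNP cohort with one 50%-Va QTL; shared across tests."""
    return mk.SimConfig(
        n_individuals=150,
        n_snps=400,
        n_chromosomes=4,
        maf_range=(0.1, 0.5),
        trait_names=["kappa_cn", "beta_lg", "minor_n"],
        trait_clusters={"kappa_cn": 1, "beta_lg": 2, "minor_n": 2},
        h2={"kappa_cn": 0.6, "beta_lg": 0.5, "minor_n": 0.3},
        qtls=[mk.QtlSpec(chrom=2, pos=5_000_000, effects={"kappa_cn": 0.5})],
        n_herds=10,
        dim_classes=5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config) -> mk.SyntheticCohort:
    return mk.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def toy_annotation(small_cohort, small_config):
    return mk.make_toy_annotation(small_cohort.genotypes, small_config)


def make_genotypes(dosage, chrom=None, pos=None) -> mk.GenotypeMatrix:
    """Hand-built GenotypeMatrix from a dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    chrom = chrom if chrom is not None else [1] * m
    pos = pos if pos is not None else [1000 * (k + 1) for k in range(m)]
    snp_map = pd.DataFrame(
        {
            "snp": [f"s{k}" for k in range(m)],
            "chrom": chrom,
            "pos": pos,
            "a1": "A",
            "a2": "B",
        }
    )
    return mk.GenotypeMatrix(
        dosage=dosage, snp_map=snp_map, sample_ids=[f"i{i}" for i in range(n)]
    )
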