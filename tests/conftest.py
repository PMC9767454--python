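import numpy as np
import pandas as pd
import pytest

from triomr import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def snp_cohort():
    """Small SNP-level cohort reused by genotype-touching tests."""
    cfg = SimConfig.moba_like(n_families=800, n_snps=120, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Score-level cohort under the global null."""
    return simulate_cohort(SimConfig.global_null(n_families=20000, seed=7))


def make_geno(dosages, positions=None, chrom=1, effect="A", other="G"):
    """GenotypeMatrix from a raw dosage array (testing helper)."""
    from triomr import GenotypeMatrix

    dosages = np.asarray(dosages)
    n, m = dosages.shape
    positions = positions if positions is not None else (1 + np.arange(m) * 1000)
    snps = pd.DataFrame({
        "snp_id": [f"rs{j}" for j in range(m)],
        "chrom": chrom, "pos": positions,
        "effect_allele": effect, "other_allele": other,
    })
    return GenotypeMatrix(ids=np.array([f"i{i}" for i in range(n)]),
                          snps=snps, dosages=dosages)
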