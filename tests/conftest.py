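import numpy as np
import pandas as pd
import pytest

from slepipe import GenotypeMatrix, RiskSnp, SimulationConfig, simulate_cohort
from slepipe.containers import CASE, CONTROL


def make_matrix(genotypes, status=None, chrom=None, pos=None):
    """Build a GenotypeMatrix from a plain array with minimal metadata."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    snps = pd.DataFrame({
        "snp_id": [f"s{j}" for j in range(m)],
        "chrom": chrom if chrom is not None else [1] * m,
        "pos": pos if pos is not None else [1000 * (j + 1) for j in range(m)],
        "allele1": "A",
        "allele2": "G",
    })
    samples = pd.DataFrame({
        "sample_id": [f"i{i}" for i in range(n)],
        "status": status if status is not None else [CONTROL] * n,
        "stage": "gwas",
    })
    return GenotypeMatrix(g, snps, samples)


@pytest.fixture(scope="session")
def null_cohort():
    """A moderate cohort with no risk SNPs (null model)."""
    cfg = SimulationConfig(n_cases=500, n_controls=500, n_snps=200,
                           n_blocks=40, seed=11, missing_rate=0.01)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def risk_cohort():
    """A cohort with one strong causal eQTL SNP."""
    cfg = SimulationConfig(
        n_cases=891, n_controls=3384, n_snps=200, n_blocks=40, seed=5,
        risk_snps=(RiskSnp(10, 1.6, 0.8),), n_expr_samples=90,
        probes_per_region=3)
    return cfg, simulate_cohort(cfg)
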