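import numpy as np
import pytest

from triefdr import (
    DosageMatrix,
    EqtlMap,
    ExpressionMatrix,
    NullPool,
    PhenotypeVector,
    Scenario,
    simulate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def worked_pools():
    """Hand-counted observed/simulated pools used across the FDR tests."""
    obs = {"s1": 0.01, "s2": 0.2, "s3": 0.6, "s4": 0.9}
    sim = np.array([0.05, 0.3, 0.55, 0.7, 0.95])
    pool = NullPool(sim, np.array([5]), n=1, seed=0)
    return obs, sim, pool


@pytest.fixture
def toy_trio():
    """A tiny aligned genotype/expression/phenotype trio (4 samples)."""
    samples = ["A", "B", "C", "D"]
    dosages = DosageMatrix(
        samples, ["snp1", "snp2", "snp3"],
        np.array([[0, 1, 2], [1, 1, 0], [2, 0, 1], [0, 2, 2]], dtype=float),
    )
    expr = ExpressionMatrix(
        samples, ["g1", "g2"],
        np.array([[0.5, -1.2], [1.5, 0.3], [2.1, 0.9], [-0.3, 1.1]]),
    )
    pheno = PhenotypeVector(
        samples, np.array([1.0, 2.0, 0.5, 3.0]),
        covariates=np.array([[0.1], [0.2], [0.3], [0.4]]),
        covariate_names=["age"],
    )
    eqtl = EqtlMap.from_tuples(
        [("snp1", "g1", 1e-6), ("snp1", "g2", 1e-6),
         ("snp2", "g1", 1e-6), ("snp3", "g2", 0.5)]
    )
    return dosages, expr, pheno, eqtl


@pytest.fixture(scope="session")
def small_study():
    """Seeded 30-sample, 40-SNP, 8-gene study for triangle-level tests."""
    sc = Scenario(
        n_samples=30, n_snps=40, n_genes=8, ld_block_size=4,
        eqtl_fraction=0.5, eqtl_effect=1.5, n_causal_genes=2,
        phenotype_r2=0.5, seed=7,
    )
    return simulate_dataset(sc)


@pytest.fixture(scope="session")
def medium_study():
    """Seeded 50-sample, 20-SNP, 10-gene study for the eQTL-scan oracle."""
    sc = Scenario(
        n_samples=50, n_snps=20, n_genes=10, ld_block_size=5,
        eqtl_fraction=0.5, eqtl_effect=1.5, n_causal_genes=2,
        phenotype_r2=0.4, seed=11,
    )
    return simulate_dataset(sc)
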