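"""Synthetic genotype / expression / phenotype generator with truth labels.

Generates datasets with the statistical structure the triangle method
assumes: LD-block genotypes, gene expression with a shared low-rank factor
structure (the gene-gene correlation the permutation scheme must preserve)
plus planted eQTL effects, and a phenotype mediated by the expression of a
set of causal genes. ``phenotype_r2 = 0`` gives the pure-null scenario — a
phenotype independent of everything — used to study false discoveries.

Genotypes use a haplotype-copying scheme: within an LD block each haplotype
allele copies the previous SNP's allele with probability ``ld_r`` and is
drawn fresh from its own allele frequency otherwise. This guarantees valid
{0,1,2} dosages and gives adjacent-SNP correlation close to ``ld_r``.

Expression variance bookkeeping: each gene's factor loadings and residual
noise are scaled so the non-genetic variance is 1; two genes both loading
l on the same factor then correlate at ~l^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import DosageMatrix, EqtlMap, ExpressionMatrix, PhenotypeVector

__all__ = [
    "Scenario",
    "TruthLabels",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_phenotype",
    "simulate_dataset",
    "expand_signal_to_blocks",
]


@dataclass
class Scenario:
    """Parameters of one synthetic study.

    Defaults describe the desk-scale study used throughout the test suite:
    200 samples, 3000 SNPs in 10-SNP LD blocks, 300 genes, 30% of genes
    carrying one planted eQTL of effect 1 (per dosage unit, against unit
    non-genetic expression variance), and a pure-null phenotype. Set
    ``phenotype_r2`` > 0 for a mediated phenotype driven by
    ``n_causal_genes`` genes.
    """

    n_samples: int = 200
    n_snps: int = 3000
    n_genes: int = 300
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_block_size: int = 10
    ld_r: float = 0.8
    n_factors: int = 5
    max_factor_var: float = 0.5
    eqtl_fraction: float = 0.3
    eqtl_effect: float = 1.0
    n_causal_genes: int = 10
    phenotype_r2: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_snps", "n_genes", "ld_block_size", "n_factors"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.ld_r < 1.0):
            raise ValueError("ld_r must lie in [0, 1)")
        if not (0.0 <= self.eqtl_fraction <= 1.0):
            raise ValueError("eqtl_fraction must lie in [0, 1]")
        if not (0.0 <= self.phenotype_r2 < 1.0):
            raise ValueError("phenotype_r2 must lie in [0, 1)")
        if not (0.0 <= self.max_factor_var < 1.0):
            raise ValueError("max_factor_var must lie in [0, 1)")

    def with_(self, **kwargs) -> "Scenario":
        return replace(self, **kwargs)


@dataclass
class TruthLabels:
    """Ground truth of a simulated dataset.

    ``signal_snps`` — the SNPs the triangle method should recover — are
    exactly the planted eQTLs of the causal genes.
    """

    true_eqtl_pairs: set[tuple[str, str]]
    causal_genes: set[str]
    signal_snps: set[str] = field(init=False)

    def __post_init__(self) -> None:
        self.signal_snps = {
            snp for snp, gene in self.true_eqtl_pairs if gene in self.causal_genes
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"kind": "eqtl_pair", "snp_id": s, "gene_id": g}
            for s, g in sorted(self.true_eqtl_pairs)
        ]
        rows += [{"kind": "causal_gene", "snp_id": "", "gene_id": g}
                 for g in sorted(self.causal_genes)]
        return pd.DataFrame(rows, columns=["kind", "snp_id", "gene_id"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TruthLabels":
        pairs = {
            (str(r.snp_id), str(r.gene_id))
            for r in df[df["kind"] == "eqtl_pair"].itertuples()
        }
        causal = {str(r.gene_id) for r in df[df["kind"] == "causal_gene"].itertuples()}
        return cls(pairs, causal)


def simulate_genotypes(sc: Scenario, rng: np.random.Generator) -> DosageMatrix:
    """LD-block genotypes: dosages in {0, 1, 2} with per-SNP MAF from maf_range."""
    n, p = sc.n_samples, sc.n_snps
    freqs = rng.uniform(sc.maf_range[0], sc.maf_range[1], size=p)
    fresh = rng.random((2, n, p)) < freqs  # independent draws at each SNP
    copy = rng.random((2, n, p)) < sc.ld_r
    block_start = (np.arange(p) % sc.ld_block_size) == 0
    copy[:, :, block_start] = False  # blocks are independent of each other
    H = np.empty((2, n, p), dtype=bool)
    H[:, :, 0] = fresh[:, :, 0]
    for j in range(1, p):
        H[:, :, j] = np.where(copy[:, :, j], H[:, :, j - 1], fresh[:, :, j])
    dosage = H.sum(axis=0).astype(float)
    sample_ids = [f"S{i:04d}" for i in range(n)]
    snp_ids = [f"rs{j:05d}" for j in range(p)]
    return DosageMatrix(sample_ids, snp_ids, dosage)


def simulate_expression(
    dosages: DosageMatrix, sc: Scenario, rng: np.random.Generator
) -> tuple[ExpressionMatrix, set[tuple[str, str]]]:
    """Factor-structured expression with planted eQTL effects.

    expression_g = beta * dosage_{snp(g)} (planted genes only)
                   + loadings_g . factors + noise,
    with loadings and noise scaled so the non-genetic variance is 1.
    """
    n, g = dosages.n_samples, sc.n_genes
    n_eqtl = int(round(sc.eqtl_fraction * g))
    eqtl_genes = rng.choice(g, size=n_eqtl, replace=False)
    replace_snps = dosages.n_snps < n_eqtl
    eqtl_snps = rng.choice(dosages.n_snps, size=n_eqtl, replace=replace_snps)

    factors = rng.standard_normal((n, sc.n_factors))
    raw = rng.standard_normal((g, sc.n_factors))
    # per-gene share of unit variance explained by the factors
    factor_var = rng.uniform(0.0, sc.max_factor_var, size=g)
    norms = np.linalg.norm(raw, axis=1, keepdims=True)
    loadings = raw / np.where(norms > 0, norms, 1.0) * np.sqrt(factor_var)[:, None]
    noise_sd = np.sqrt(1.0 - factor_var)

    E = factors @ loadings.T + rng.standard_normal((n, g)) * noise_sd
    E[:, eqtl_genes] += sc.eqtl_effect * dosages.values[:, eqtl_snps]

    gene_ids = [f"G{j:04d}" for j in range(g)]
    pairs = {
        (dosages.snp_ids[s], gene_ids[j]) for s, j in zip(eqtl_snps, eqtl_genes)
    }
    return ExpressionMatrix(list(dosages.sample_ids), gene_ids, E), pairs


def simulate_phenotype(
    expr: ExpressionMatrix,
    sc: Scenario,
    rng: np.random.Generator,
    candidate_genes: list[str] | None = None,
) -> tuple[PhenotypeVector, set[str]]:
    """Expression-mediated phenotype: y = sum_g gamma_g * expression_g + noise.

    The causal-gene contribution is scaled to explain ``phenotype_r2`` of
    the phenotype variance. With ``phenotype_r2 = 0`` the phenotype is pure
    standard-normal noise, independent of everything, and no gene is causal.
    ``candidate_genes`` restricts where causal genes are drawn from (by
    default all genes).
    """
    if sc.n_causal_genes > expr.n_genes:
        raise ValueError("n_causal_genes exceeds number of genes")
    sample_ids = list(expr.sample_ids)
    if sc.phenotype_r2 == 0.0:
        y = rng.standard_normal(expr.n_samples)
        return PhenotypeVector(sample_ids, y), set()

    pool = list(candidate_genes) if candidate_genes else list(expr.gene_ids)
    if len(pool) < sc.n_causal_genes:
        pool = list(expr.gene_ids)
    causal = sorted(rng.choice(pool, size=sc.n_causal_genes, replace=False).tolist())
    idx = [expr.gene_ids.index(gid) for gid in causal]
    # balanced mediation: equal-magnitude effects with random signs, so each
    # causal gene carries a comparable share of the heritable variance
    gamma = rng.choice([-1.0, 1.0], size=sc.n_causal_genes)
    signal = expr.values[:, idx] @ gamma
    sig_var = signal.var()
    if sig_var == 0:
        raise ValueError("causal-gene signal has zero variance")
    noise_sd = np.sqrt(sig_var * (1.0 - sc.phenotype_r2) / sc.phenotype_r2)
    y = signal + rng.standard_normal(expr.n_samples) * noise_sd
    return PhenotypeVector(sample_ids, y), set(causal)


def expand_signal_to_blocks(
    dosages: DosageMatrix, truth: TruthLabels, sc: Scenario
) -> set[str]:
    """Signal SNPs plus their LD-block mates.

    A SNP in the same LD block as a planted signal SNP is correlated with
    it and hence genuinely (if indirectly) associated with the phenotype;
    calibration harnesses should not count its discovery as false.
    """
    block = {snp: j // sc.ld_block_size for j, snp in enumerate(dosages.snp_ids)}
    signal_blocks = {block[s] for s in truth.signal_snps if s in block}
    return {s for s, b in block.items() if b in signal_blocks}


def simulate_dataset(
    sc: Scenario, rng: np.random.Generator | None = None
) -> tuple[DosageMatrix, ExpressionMatrix, PhenotypeVector, TruthLabels]:
    """Generate one complete study: genotypes, expression, phenotype, truth.

    When the phenotype is mediated (``phenotype_r2`` > 0), causal genes are
    drawn from the genes carrying a planted eQTL whenever enough exist —
    the genotype -> expression -> phenotype path is the structure the
    triangle method targets.
    """
    if rng is None:
        rng = np.random.default_rng(sc.seed)
    dosages = simulate_genotypes(sc, rng)
    expr, pairs = simulate_expression(dosages, sc, rng)
    eqtl_gene_ids = sorted({g for _, g in pairs})
    pheno, causal = simulate_phenotype(expr, sc, rng, candidate_genes=eqtl_gene_ids)
    return dosages, expr, pheno, TruthLabels(pairs, causal)
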