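"""Permutation null for the triangle method.

The only object ever permuted is the phenotype (with its covariate rows
relabeled in sync); genotype and expression stay fixed, so the gene-gene
and SNP-SNP correlation structure of the data — which the selected-SNP
p-values are conditioned on — is preserved exactly in every replicate. The
eQTL map is passed in and never recomputed: it does not involve the
phenotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import DosageMatrix, EqtlMap, ExpressionMatrix, PhenotypeVector, Thresholds
from .triangle import run_triangle

__all__ = ["NullPool", "permute_phenotype", "build_null"]

logger = logging.getLogger(__name__)


@dataclass
class NullPool:
    """Pooled p-values from n permuted-phenotype triangle runs.

    ``per_replicate_counts[s]`` is m_{0,s}, the number of SNPs the triangle
    selected for permutation replicate s; ``M0`` is their sum and the size
    of the pool.
    """

    pooled_pvalues: np.ndarray
    per_replicate_counts: np.ndarray
    n: int
    seed: int

    def __post_init__(self) -> None:
        self.pooled_pvalues = np.asarray(self.pooled_pvalues, dtype=float)
        self.per_replicate_counts = np.asarray(self.per_replicate_counts, dtype=int)
        if len(self.per_replicate_counts) != self.n:
            raise ValueError("per_replicate_counts must have length n")
        if self.per_replicate_counts.sum() != len(self.pooled_pvalues):
            raise ValueError("pool size does not equal sum of per-replicate counts")
        if len(self.pooled_pvalues) and not (
            (self.pooled_pvalues > 0).all() and (self.pooled_pvalues <= 1).all()
        ):
            raise ValueError("pooled p-values must lie in (0, 1]")

    @property
    def M0(self) -> int:
        return int(self.per_replicate_counts.sum())


def permute_phenotype(
    pheno: PhenotypeVector, rng: np.random.Generator, permutation: np.ndarray | None = None
) -> PhenotypeVector:
    """Relabel phenotype (and covariate) rows by a uniform random permutation.

    Sample ids keep their original order — the permutation moves trait
    values relative to the fixed genotype/expression sample order, which is
    what breaks any genotype-phenotype association. ``permutation`` is a
    test hook to force a specific relabeling (e.g. the identity).
    """
    if pheno.n_samples == 0:
        raise ValueError("cannot permute an empty phenotype")
    if permutation is None:
        permutation = rng.permutation(pheno.n_samples)
    permutation = np.asarray(permutation)
    cov = None if pheno.covariates is None else pheno.covariates[permutation]
    return PhenotypeVector(
        list(pheno.sample_ids), pheno.y[permutation], cov, list(pheno.covariate_names)
    )


def replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """Independent, order-invariant random stream for one replicate."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(replicate,)))


def build_null(
    expr: ExpressionMatrix,
    pheno: PhenotypeVector,
    dosages: DosageMatrix,
    eqtl_map: EqtlMap,
    th: Thresholds,
    n: int = 1000,
    seed: int = 0,
) -> NullPool:
    """Run the identical triangle filter on ``n`` permuted phenotypes.

    Each replicate draws its own permutation from a substream of ``seed``
    (so results do not depend on execution order), applies
    :func:`run_triangle` with the same eQTL map and thresholds as the
    observed analysis, and contributes its SNP p-values to the pool. A
    replicate whose cascade empties out contributes m_{0,s} = 0.
    """
    if n < 1:
        raise ValueError("need at least one permutation replicate")
    pooled: list[np.ndarray] = []
    counts = np.zeros(n, dtype=int)
    for s in range(n):
        rng = replicate_rng(seed, s)
        perm_pheno = permute_phenotype(pheno, rng)
        res = run_triangle(expr, perm_pheno, dosages, eqtl_map, th)
        counts[s] = res.m
        if res.m:
            pooled.append(np.fromiter(res.snp_pvalues.values(), dtype=float))
    pool = np.concatenate(pooled) if pooled else np.empty(0)
    logger.info("permutation null: n=%d replicates, M0=%d pooled p-values", n, counts.sum())
    return NullPool(pooled_pvalues=pool, per_replicate_counts=counts, n=n, seed=seed)
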