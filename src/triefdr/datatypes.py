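"""Core data containers for the genotype / expression / phenotype triangle.

All sample-indexed containers keep samples on axis 0 in a shared order; the
loaders in :mod:`triefdr.io` are responsible for establishing that order.
Identifiers are opaque strings — the method needs no genomic coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DosageMatrix",
    "ExpressionMatrix",
    "PhenotypeVector",
    "EqtlMap",
    "Thresholds",
]


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dupes[:5]}")
    return ids


@dataclass
class DosageMatrix:
    """Genotype dosages, samples x SNPs, each entry the ALT/minor-allele count.

    Entries are real numbers in [0, 2]; fractional values arise from
    mean-imputation of missing genotypes.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    values: np.ndarray  # (n_samples, n_snps) float

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample ids")
        self.snp_ids = _check_unique(self.snp_ids, "SNP ids")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError(
                f"dosage matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dosage matrix contains non-finite entries")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        self._snp_index = {s: j for j, s in enumerate(self.snp_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def snp_column(self, snp_id: str) -> np.ndarray:
        return self.values[:, self._snp_index[snp_id]]

    def snp_columns(self, snp_ids: Sequence[str]) -> np.ndarray:
        idx = [self._snp_index[s] for s in snp_ids]
        return self.values[:, idx]

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency, folded into [0, 0.5]."""
        freq = self.values.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def take_samples(self, order: Sequence[int]) -> "DosageMatrix":
        return DosageMatrix(
            [self.sample_ids[i] for i in order], list(self.snp_ids), self.values[list(order)]
        )


@dataclass
class ExpressionMatrix:
    """Quantitative gene expression, samples x genes."""

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray  # (n_samples, n_genes) float

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample ids")
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"expression matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite entries")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def take_samples(self, order: Sequence[int]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            [self.sample_ids[i] for i in order], list(self.gene_ids), self.values[list(order)]
        )


@dataclass
class PhenotypeVector:
    """A quantitative trait per sample, with optional covariates.

    Covariate rows are index-locked to ``y``: any permutation of sample
    positions must move them together (see :func:`triefdr.permnull.permute_phenotype`).
    """

    sample_ids: list[str]
    y: np.ndarray  # (n_samples,)
    covariates: Optional[np.ndarray] = None  # (n_samples, c)
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample ids")
        self.y = np.asarray(self.y, dtype=float).ravel()
        if len(self.y) != len(self.sample_ids):
            raise ValueError("phenotype length does not match number of samples")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("phenotype contains non-finite values")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != len(self.y):
                raise ValueError("covariate rows do not match phenotype length")
            if not self.covariate_names:
                self.covariate_names = [f"cov{i}" for i in range(self.covariates.shape[1])]
            if len(self.covariate_names) != self.covariates.shape[1]:
                raise ValueError("covariate_names length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_covariates(self) -> int:
        return 0 if self.covariates is None else self.covariates.shape[1]

    def take_samples(self, order: Sequence[int]) -> "PhenotypeVector":
        order = list(order)
        cov = None if self.covariates is None else self.covariates[order]
        return PhenotypeVector(
            [self.sample_ids[i] for i in order], self.y[order], cov, list(self.covariate_names)
        )


class EqtlMap:
    """SNP <-> gene association records with p-values.

    This is the fixed "genetic machinery" of the analysis: it is computed (or
    loaded) once per dataset and queried, never recomputed, inside the
    permutation loop.
    """

    def __init__(self, records: pd.DataFrame):
        records = pd.DataFrame(records, columns=["snp_id", "gene_id", "pvalue"]).copy()
        records["snp_id"] = records["snp_id"].astype(str)
        records["gene_id"] = records["gene_id"].astype(str)
        records["pvalue"] = records["pvalue"].astype(float)
        if records.duplicated(["snp_id", "gene_id"]).any():
            raise ValueError("duplicate (snp_id, gene_id) pairs in eQTL map")
        if len(records) and not (
            (records["pvalue"] > 0).all() and (records["pvalue"] <= 1).all()
        ):
            raise ValueError("eQTL p-values must lie in (0, 1]")
        self.records = records.reset_index(drop=True)

    @classmethod
    def from_tuples(cls, tuples) -> "EqtlMap":
        return cls(pd.DataFrame(tuples, columns=["snp_id", "gene_id", "pvalue"]))

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EqtlMap):
            return NotImplemented
        a = self.records.sort_values(["snp_id", "gene_id"]).reset_index(drop=True)
        b = other.records.sort_values(["snp_id", "gene_id"]).reset_index(drop=True)
        return a.equals(b)

    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.records["snp_id"], self.records["gene_id"]))

    def restrict(self, p_snp_gene: float) -> "EqtlMap":
        """Records passing strictly below the SNP-gene cutoff."""
        return EqtlMap(self.records[self.records["pvalue"] < p_snp_gene])


@dataclass
class Thresholds:
    """Filter cutoffs of the triangle method.

    All p-value thresholds are applied strictly (``<``); ties at the cutoff
    are excluded. ``min_gene_count`` > 1 activates the hub-eQTL variant
    (SNPs must regulate several phenotype-associated genes).
    """

    p_gene_phenotype: float = 0.05
    p_snp_gene: float = 1e-4
    p_snp_phenotype: float = 1.0
    min_gene_count: int = 1
    maf_min: float = 0.05

    def __post_init__(self) -> None:
        for name in ("p_gene_phenotype", "p_snp_gene", "p_snp_phenotype"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if int(self.min_gene_count) < 1:
            raise ValueError("min_gene_count must be >= 1")
        self.min_gene_count = int(self.min_gene_count)
        if not (0.0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must lie in [0, 0.5)")
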