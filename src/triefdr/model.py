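"""Model / results interface to the triangle + empirical-FDR analysis.

``TriangleModel`` holds the aligned study data (genotype dosages, gene
expression, phenotype, and the eQTL map that plays the role of the fixed
genetic machinery) together with the filter thresholds. ``fit()`` runs the
observed triangle analysis, builds the permutation null, estimates the
empirical FDR, and returns an :class:`EfdrResults` carrying the per-SNP
table, the diagnostics (pi0, M, M0) and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .assoc import compute_eqtl_map
from .datatypes import DosageMatrix, EqtlMap, ExpressionMatrix, PhenotypeVector, Thresholds
from .efdr import FdrTable, efdr_qvalues, qq_coordinates
from .permnull import NullPool, build_null
from .triangle import TriangleResult, run_triangle

__all__ = ["TriangleModel", "EfdrResults"]


class TriangleModel:
    """eQTL-informed SNP prioritization with permutation-based FDR.

    Parameters
    ----------
    dosages, expression, phenotype
        Sample-aligned study data (use :func:`triefdr.io.load_dataset` to
        align from files).
    eqtl_map : EqtlMap, optional
        Precomputed SNP-gene association records (e.g. a database export).
        If omitted, an exhaustive scan at ``thresholds.p_snp_gene`` is run
        once at construction — never inside the permutation loop.
    thresholds : Thresholds, optional
        Filter cutoffs; defaults follow the method's standard application
        (gene-phenotype 0.05, SNP-gene 1e-4, no final-arm cutoff).
    """

    def __init__(
        self,
        dosages: DosageMatrix,
        expression: ExpressionMatrix,
        phenotype: PhenotypeVector,
        eqtl_map: Optional[EqtlMap] = None,
        thresholds: Optional[Thresholds] = None,
    ):
        if expression.sample_ids != phenotype.sample_ids or (
            dosages.sample_ids != phenotype.sample_ids
        ):
            raise ValueError(
                "inputs are not sample-aligned; load them with triefdr.io.load_dataset"
            )
        self.dosages = dosages
        self.expression = expression
        self.phenotype = phenotype
        self.thresholds = thresholds or Thresholds()
        if eqtl_map is None:
            eqtl_map = compute_eqtl_map(dosages, expression, self.thresholds.p_snp_gene)
        self.eqtl_map = eqtl_map

    @classmethod
    def from_files(
        cls,
        genotype_path,
        expression_path,
        phenotype_path,
        eqtl_path=None,
        thresholds: Optional[Thresholds] = None,
        missing_policy: str = "mean",
    ) -> "TriangleModel":
        from . import io

        th = thresholds or Thresholds()
        dosages, expr, pheno, eqtl = io.load_dataset(
            genotype_path, expression_path, phenotype_path, eqtl_path,
            maf_min=th.maf_min, missing_policy=missing_policy,
        )
        return cls(dosages, expr, pheno, eqtl, th)

    def run_observed(self) -> TriangleResult:
        """The triangle filter on the unpermuted phenotype."""
        return run_triangle(
            self.expression, self.phenotype, self.dosages, self.eqtl_map, self.thresholds
        )

    def fit(
        self,
        n_permutations: int = 1000,
        seed: int = 0,
        lam: float = 0.5,
        conservative: bool = False,
    ) -> "EfdrResults":
        """Observed analysis + permutation null + empirical FDR estimation."""
        observed = self.run_observed()
        pool = build_null(
            self.expression, self.phenotype, self.dosages, self.eqtl_map,
            self.thresholds, n=n_permutations, seed=seed,
        )
        meta = {
            "seed": seed,
            "p_gene_phenotype": self.thresholds.p_gene_phenotype,
            "p_snp_gene": self.thresholds.p_snp_gene,
            "p_snp_phenotype": self.thresholds.p_snp_phenotype,
            "min_gene_count": self.thresholds.min_gene_count,
        }
        table = efdr_qvalues(observed, pool, lam=lam, conservative=conservative, meta=meta)
        return EfdrResults(model=self, observed=observed, null_pool=pool, fdr=table)


@dataclass
class EfdrResults:
    """Fitted results: prioritized SNPs with naive and empirical FDR."""

    model: TriangleModel
    observed: TriangleResult
    null_pool: NullPool
    fdr: FdrTable

    @property
    def table(self):
        return self.fdr.table

    @property
    def pi0(self) -> float:
        return self.fdr.meta.get("pi0_hat", np.nan)

    @property
    def m(self) -> int:
        return self.observed.m

    @property
    def M0(self) -> int:
        return self.null_pool.M0

    def significant(self, q_max: float = 0.15):
        """Rows called significant at q_efdr <= q_max."""
        return self.table[self.table["q_efdr"] <= q_max]

    def qq_observed(self):
        """QQ coordinates (-log10) of the observed prioritized p-values."""
        return qq_coordinates(self.table["p_obs"].to_numpy())

    def qq_null(self):
        """QQ coordinates (-log10) of the pooled permutation-null p-values."""
        return qq_coordinates(self.null_pool.pooled_pvalues)

    def save(self, path) -> None:
        from . import io

        io.write_results(self.fdr, path)

    def summary(self) -> str:
        meta = self.fdr.meta
        lines = [
            "Triangle empirical-FDR results",
            "==============================",
            f"samples                 {self.model.phenotype.n_samples}",
            f"genes / SNPs            {self.model.expression.n_genes} / {self.model.dosages.n_snps}",
            f"eQTL map records        {len(self.model.eqtl_map)}",
            f"genes selected          {len(self.observed.selected_genes)}"
            f" (p < {meta.get('p_gene_phenotype')})",
            f"SNPs prioritized (m)    {self.m}",
            f"permutations (n)        {meta.get('n_permutations')}",
            f"null pool size (M0)     {self.M0}",
            f"lambda / pi0_hat        {meta.get('lambda')} / {self.pi0:.4g}",
            f"SNPs at q_efdr <= 0.15  {len(self.significant(0.15))}",
            "",
        ]
        head = self.table.head(10)
        if len(head):
            lines.append(head.to_string(index=False,
                                        float_format=lambda v: f"{v:.4g}"))
        else:
            lines.append("(no SNPs survived the triangle filter)")
        return "\n".join(lines)
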