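"""The three-step integrative "triangle" filter.

Step 1: genes whose expression associates with the phenotype
(p < p_gene_phenotype). Step 2: SNPs that are eQTLs of at least
``min_gene_count`` of those genes (p < p_snp_gene in the eQTL map). Step 3:
the surviving SNPs are tested against the phenotype; those with
p < p_snp_phenotype form the prioritized set with their observed p-values.

Every threshold is strict (``<``); ties at a cutoff are excluded. A SNP
supported by several selected genes is tested against the phenotype once
and contributes a single p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .assoc import AssocResult, mass_simple_regression
from .datatypes import DosageMatrix, EqtlMap, ExpressionMatrix, PhenotypeVector, Thresholds

__all__ = ["TriangleResult", "select_genes", "select_snps", "run_triangle"]

logger = logging.getLogger(__name__)


@dataclass
class TriangleResult:
    """Prioritized SNPs with their phenotype-association p-values.

    ``provenance`` maps each SNP to the selected genes whose eQTL it is;
    ``m`` is the pool size entering the FDR estimation.
    """

    selected_genes: set[str]
    snp_pvalues: dict[str, float]
    provenance: dict[str, set[str]] = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.snp_pvalues)

    def sorted_pvalues(self) -> np.ndarray:
        return np.sort(np.fromiter(self.snp_pvalues.values(), dtype=float))


def select_genes(gene_assoc: AssocResult, p_gene_phenotype: float) -> set[str]:
    """Genes associated with the phenotype strictly below the cutoff."""
    mask = gene_assoc.pvalue < p_gene_phenotype
    return {gene_assoc.feature_ids[j] for j in np.flatnonzero(mask)}


def select_snps(
    eqtl_map: EqtlMap,
    genes: set[str],
    p_snp_gene: float,
    min_gene_count: int = 1,
) -> tuple[set[str], dict[str, set[str]]]:
    """SNPs that are eQTLs of at least ``min_gene_count`` selected genes.

    Returns the SNP set and a provenance mapping snp -> supporting genes
    (exactly those selected genes whose map record passes the cutoff).
    """
    if not genes:
        return set(), {}
    rec = eqtl_map.records
    mask = (rec["pvalue"].to_numpy() < p_snp_gene) & rec["gene_id"].isin(genes).to_numpy()
    hits = rec[mask]
    provenance: dict[str, set[str]] = {}
    for snp, gene in zip(hits["snp_id"], hits["gene_id"]):
        provenance.setdefault(snp, set()).add(gene)
    provenance = {s: g for s, g in provenance.items() if len(g) >= min_gene_count}
    return set(provenance), provenance


def run_triangle(
    expr: ExpressionMatrix,
    pheno: PhenotypeVector,
    dosages: DosageMatrix,
    eqtl_map: EqtlMap,
    th: Thresholds,
) -> TriangleResult:
    """Run the full triangle filter and return the prioritized SNP set.

    The eQTL map is taken as given — it encodes the genotype-expression
    machinery and must be identical between the observed analysis and every
    permutation replicate.
    """
    if expr.sample_ids != pheno.sample_ids or dosages.sample_ids != pheno.sample_ids:
        raise ValueError("expression, phenotype and dosage samples are not aligned")

    gene_assoc = mass_simple_regression(
        expr.values, pheno.y, pheno.covariates, feature_ids=expr.gene_ids
    )
    genes = select_genes(gene_assoc, th.p_gene_phenotype)
    logger.info("triangle stage 1: %d/%d genes pass p < %g",
                len(genes), expr.n_genes, th.p_gene_phenotype)

    snps, provenance = select_snps(eqtl_map, genes, th.p_snp_gene, th.min_gene_count)
    logger.info("triangle stage 2: %d SNPs are eQTLs of >= %d selected gene(s) at p < %g",
                len(snps), th.min_gene_count, th.p_snp_gene)

    snp_pvalues: dict[str, float] = {}
    if snps:
        snp_list = sorted(snps)
        snp_assoc = mass_simple_regression(
            dosages.snp_columns(snp_list), pheno.y, pheno.covariates, feature_ids=snp_list
        )
        keep = snp_assoc.pvalue < th.p_snp_phenotype
        snp_pvalues = {
            snp_list[j]: float(snp_assoc.pvalue[j]) for j in np.flatnonzero(keep)
        }
    provenance = {s: provenance[s] for s in snp_pvalues}
    logger.info("triangle stage 3: %d SNPs pass p < %g against the phenotype",
                len(snp_pvalues), th.p_snp_phenotype)
    return TriangleResult(selected_genes=genes, snp_pvalues=snp_pvalues, provenance=provenance)
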