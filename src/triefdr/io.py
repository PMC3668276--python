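"""Readers and writers for the tab-delimited formats the tool touches.

Dialects
--------
* genotype: first column ``snp_id``, remaining columns sample ids, cells
  dosages in [0, 2] (``NA`` / empty = missing); or a VCF, from which the
  dosage is the ALT-allele count of the GT field.
* expression: first column ``gene_id``, remaining columns sample ids.
* phenotype: columns ``sample_id``, ``phenotype``, then covariates.
* eQTL map: columns ``snp_id``, ``gene_id``, ``pvalue``.
* results: commented header (run metadata) + per-SNP FDR table.

``load_dataset`` aligns everything to the intersection of sample ids, in
the phenotype file's order (the phenotype defines the canonical order).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import DosageMatrix, EqtlMap, ExpressionMatrix, PhenotypeVector
from .efdr import FdrTable
from .permnull import NullPool

__all__ = [
    "read_genotypes", "write_genotypes", "read_expression", "write_expression",
    "read_phenotype", "write_phenotype", "read_eqtl_map", "write_eqtl_map",
    "read_vcf_dosages", "load_dataset", "write_results", "read_results",
    "write_null_pool", "read_null_pool",
]

logger = logging.getLogger(__name__)

_NA_STRINGS = {"", "NA", "NaN", "nan", "na", "."}


def _read_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001 - rewrap with filename
        raise ValueError(f"cannot parse {path}: {exc}") from exc


def _to_numeric(df: pd.DataFrame, path, allow_missing: bool = False) -> pd.DataFrame:
    """Convert all cells to float, reporting the first offending coordinate.

    The final conversion goes through numpy (correctly rounded), not the
    fast pandas parser, so written values round-trip bit-exactly.
    """
    work = df.replace(list(_NA_STRINGS), np.nan) if allow_missing else df
    coerced = work.apply(pd.to_numeric, errors="coerce")  # locates bad cells only
    bad = coerced.isna() & work.notna() if allow_missing else coerced.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell {df.iat[r, c]!r} at row {r + 2}, "
            f"column {df.columns[c]!r}"
        )
    return work.astype(float)


# ---------------------------------------------------------------------------
# genotype

def read_genotypes(path, missing_policy: str = "mean") -> DosageMatrix:
    """Read a tab-delimited dosage matrix (rows = SNPs) or a VCF.

    ``missing_policy``: "mean" imputes the per-SNP mean of non-missing
    dosages; "fail" raises on any missing entry.
    """
    path = Path(path)
    if path.suffix in {".vcf", ".gz"} or path.name.endswith(".vcf.gz"):
        return read_vcf_dosages(path, missing_policy=missing_policy)
    df = _read_table(path)
    if df.columns[0] != "snp_id":
        raise ValueError(f"{path}: first genotype column must be 'snp_id', got {df.columns[0]!r}")
    snp_ids = df["snp_id"].tolist()
    vals = _to_numeric(df.drop(columns="snp_id"), path, allow_missing=True)
    values = _impute(vals.to_numpy(dtype=float).T, snp_ids, path, missing_policy)
    return DosageMatrix(list(vals.columns), snp_ids, values)


def _impute(values: np.ndarray, snp_ids, path, policy: str) -> np.ndarray:
    """values is samples x SNPs; fill NaN per SNP according to policy."""
    missing = np.isnan(values)
    if not missing.any():
        return values
    if policy == "fail":
        i, j = np.argwhere(missing)[0]
        raise ValueError(f"{path}: missing dosage for SNP {snp_ids[j]} (policy 'fail')")
    if policy != "mean":
        raise ValueError(f"unknown missing policy {policy!r}")
    all_missing = missing.all(axis=0)
    if all_missing.any():
        raise ValueError(f"{path}: SNP {snp_ids[int(np.flatnonzero(all_missing)[0])]} "
                         "has no observed dosages")
    col_means = np.nanmean(values, axis=0)
    return np.where(missing, col_means[None, :], values)


def write_genotypes(dm: DosageMatrix, path) -> None:
    df = pd.DataFrame(dm.values.T, index=pd.Index(dm.snp_ids, name="snp_id"),
                      columns=dm.sample_ids)
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_vcf_dosages(path, missing_policy: str = "mean") -> DosageMatrix:
    """Dosage = ALT allele count from the GT field of a diploid VCF."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading VCF genotypes requires cyvcf2") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, rows = [], []
    for var in vcf:
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        gt = np.asarray(var.genotypes)[:, :2]  # allele indices; -1 = missing
        dos = (gt > 0).sum(axis=1).astype(float)
        dos[(gt < 0).any(axis=1)] = np.nan
        rows.append(dos)
    values = _impute(np.asarray(rows).T, snp_ids, path, missing_policy)
    return DosageMatrix(samples, snp_ids, values)


# ---------------------------------------------------------------------------
# expression / phenotype / eqtl map

def read_expression(path) -> ExpressionMatrix:
    df = _read_table(path)
    if df.columns[0] != "gene_id":
        raise ValueError(f"{path}: first expression column must be 'gene_id', got {df.columns[0]!r}")
    gene_ids = df["gene_id"].tolist()
    vals = _to_numeric(df.drop(columns="gene_id"), path)
    return ExpressionMatrix(list(vals.columns), gene_ids, vals.to_numpy(dtype=float).T)


def write_expression(em: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(em.values.T, index=pd.Index(em.gene_ids, name="gene_id"),
                      columns=em.sample_ids)
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_phenotype(path) -> PhenotypeVector:
    df = _read_table(path)
    if list(df.columns[:2]) != ["sample_id", "phenotype"]:
        raise ValueError(f"{path}: phenotype columns must start with "
                         f"'sample_id', 'phenotype', got {list(df.columns[:2])}")
    sample_ids = df["sample_id"].tolist()
    num = _to_numeric(df.drop(columns="sample_id"), path)
    y = num["phenotype"].to_numpy(dtype=float)
    cov_cols = [c for c in num.columns if c != "phenotype"]
    cov = num[cov_cols].to_numpy(dtype=float) if cov_cols else None
    return PhenotypeVector(sample_ids, y, cov, cov_cols)


def write_phenotype(pv: PhenotypeVector, path) -> None:
    data = {"sample_id": pv.sample_ids, "phenotype": pv.y}
    for k, name in enumerate(pv.covariate_names):
        data[name] = pv.covariates[:, k]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_eqtl_map(path) -> EqtlMap:
    df = _read_table(path)
    required = ["snp_id", "gene_id", "pvalue"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"{path}: eQTL map columns must be {required}, got {list(df.columns)}")
    df["pvalue"] = df["pvalue"].astype(float)
    return EqtlMap(df[required])


def write_eqtl_map(m: EqtlMap, path) -> None:
    m.records.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# dataset loading with sample alignment

def load_dataset(
    genotype_path,
    expression_path,
    phenotype_path,
    eqtl_path=None,
    maf_min: float = 0.05,
    missing_policy: str = "mean",
) -> tuple[DosageMatrix, ExpressionMatrix, PhenotypeVector, EqtlMap | None]:
    """Load the study inputs and align samples across them.

    All sample-indexed objects are restricted to the intersection of their
    sample ids, ordered as in the phenotype file. SNPs that are monomorphic
    or below ``maf_min`` minor allele frequency (in the aligned samples)
    are dropped.
    """
    dosages = read_genotypes(genotype_path, missing_policy=missing_policy)
    expr = read_expression(expression_path)
    pheno = read_phenotype(phenotype_path)
    eqtl = read_eqtl_map(eqtl_path) if eqtl_path is not None else None

    sets = {
        str(genotype_path): set(dosages.sample_ids),
        str(expression_path): set(expr.sample_ids),
        str(phenotype_path): set(pheno.sample_ids),
    }
    shared = set.intersection(*sets.values())
    if not shared:
        raise ValueError(
            "no samples shared across inputs: "
            + "; ".join(f"{p} has {len(s)}" for p, s in sets.items())
        )
    order = [s for s in pheno.sample_ids if s in shared]
    for p, s in sets.items():
        dropped = len(s) - len(shared)
        if dropped:
            logger.info("load_dataset: dropping %d unshared sample(s) from %s", dropped, p)
    logger.info("load_dataset: %d samples in common", len(order))

    def _reindex(obj):
        pos = {sid: i for i, sid in enumerate(obj.sample_ids)}
        return obj.take_samples([pos[s] for s in order])

    dosages, expr, pheno = _reindex(dosages), _reindex(expr), _reindex(pheno)

    maf = dosages.maf()
    keep = (maf >= maf_min) & (dosages.values.std(axis=0) > 0)
    if not keep.all():
        logger.info("load_dataset: excluding %d SNP(s) with MAF < %g or monomorphic",
                    int((~keep).sum()), maf_min)
        dosages = DosageMatrix(
            list(dosages.sample_ids),
            [s for s, k in zip(dosages.snp_ids, keep) if k],
            dosages.values[:, keep],
        )
    return dosages, expr, pheno, eqtl


# ---------------------------------------------------------------------------
# results / null pool persistence

def write_results(table: FdrTable, path) -> None:
    """Write the per-SNP FDR table with a commented metadata header."""
    with open(path, "w") as fh:
        for key in sorted(table.meta):
            fh.write(f"# {key}: {table.meta[key]}\n")
        cols = ["snp_id", "genes", "p_obs", "naive_q", "efdr", "q_efdr"]
        df = table.table.reindex(columns=cols)
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_results(path) -> FdrTable:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition(":")
            meta[key.strip()] = _parse_scalar(val.strip())
            body_start = i + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t",
                     dtype=str, keep_default_na=False)
    for col in ("p_obs", "naive_q", "efdr", "q_efdr"):
        if col in df.columns:
            df[col] = df[col].astype(float)
    return FdrTable(df, meta)


def _parse_scalar(s: str):
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            pass
    if s in {"True", "False"}:
        return s == "True"
    return s


def write_null_pool(pool: NullPool, path) -> None:
    """Persist the permutation null as (replicate, pvalue) rows.

    Replicates that selected no SNP have no rows; the commented ``n``
    header lets readers restore their zero counts.
    """
    reps = np.repeat(np.arange(pool.n), pool.per_replicate_counts)
    with open(path, "w") as fh:
        fh.write(f"# n: {pool.n}\n# seed: {pool.seed}\n# M0: {pool.M0}\n")
        pd.DataFrame({"replicate": reps, "pvalue": pool.pooled_pvalues}).to_csv(
            fh, sep="\t", index=False, float_format="%.17g"
        )


def read_null_pool(path) -> NullPool:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition(":")
            meta[key.strip()] = _parse_scalar(val.strip())
            body_start = i + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t",
                     float_precision="round_trip")
    n = int(meta["n"])
    counts = np.zeros(n, dtype=int)
    if len(df):
        uniq, cnt = np.unique(df["replicate"].to_numpy(int), return_counts=True)
        counts[uniq] = cnt
    return NullPool(df["pvalue"].to_numpy(float) if len(df) else np.empty(0),
                    counts, n, int(meta.get("seed", 0)))
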