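"""File dialects: round trips, sample alignment, imputation, error reporting."""

import numpy as np
import pandas as pd
import pytest

from triefdr import (
    DosageMatrix,
    EqtlMap,
    FdrTable,
    NullPool,
    PhenotypeVector,
    Thresholds,
    efdr_qvalues,
)
from triefdr import io


def write_trio(tmp_path, dosages, expr, pheno, eqtl=None):
    paths = {
        "genotypes": tmp_path / "geno.tsv",
        "expression": tmp_path / "expr.tsv",
        "phenotype": tmp_path / "pheno.tsv",
    }
    io.write_genotypes(dosages, paths["genotypes"])
    io.write_expression(expr, paths["expression"])
    io.write_phenotype(pheno, paths["phenotype"])
    if eqtl is not None:
        paths["eqtl"] = tmp_path / "eqtl.tsv"
        io.write_eqtl_map(eqtl, paths["eqtl"])
    return paths


def test_round_trip_identity(tmp_path, toy_trio):
    dosages, expr, pheno, eqtl = toy_trio
    p = write_trio(tmp_path, dosages, expr, pheno, eqtl)
    d2, e2, p2, q2 = io.load_dataset(p["genotypes"], p["expression"],
                                     p["phenotype"], p["eqtl"], maf_min=0.0)
    assert d2.sample_ids == dosages.sample_ids and d2.snp_ids == dosages.snp_ids
    np.testing.assert_allclose(d2.values, dosages.values)
    assert e2.gene_ids == expr.gene_ids
    np.testing.assert_allclose(e2.values, expr.values)
    np.testing.assert_allclose(p2.y, pheno.y)
    np.testing.assert_allclose(p2.covariates, pheno.covariates)
    assert p2.covariate_names == pheno.covariate_names
    assert q2 == eqtl


def test_sample_intersection_follows_phenotype_order(tmp_path, toy_trio):
    dosages, expr, pheno, _ = toy_trio
    # phenotype has an extra 5th sample and a different order
    pheno5 = PhenotypeVector(
        ["E", "D", "B", "A", "C"], np.arange(5.0),
        covariates=np.arange(5.0)[:, None], covariate_names=["age"],
    )
    p = write_trio(tmp_path, dosages, expr, pheno5)
    d2, e2, p2, _ = io.load_dataset(p["genotypes"], p["expression"],
                                    p["phenotype"], maf_min=0.0)
    assert p2.sample_ids == ["D", "B", "A", "C"]  # phenotype file order
    assert d2.sample_ids == e2.sample_ids == p2.sample_ids
    for sid in p2.sample_ids:
        i = dosages.sample_ids.index(sid)
        np.testing.assert_allclose(d2.values[p2.sample_ids.index(sid)], dosages.values[i])


def test_empty_intersection_names_files(tmp_path, toy_trio):
    dosages, expr, _, _ = toy_trio
    other = PhenotypeVector(["X", "Y"], np.array([1.0, 2.0]))
    p = write_trio(tmp_path, dosages, expr, other)
    with pytest.raises(ValueError, match="no samples shared"):
        io.load_dataset(p["genotypes"], p["expression"], p["phenotype"])


def test_mean_imputation_hand_value(tmp_path):
    (tmp_path / "g.tsv").write_text(
        "snp_id\ts1\ts2\ts3\nsnpA\t0\tNA\t2\nsnpB\t1\t1\t0\n"
    )
    dm = io.read_genotypes(tmp_path / "g.tsv", missing_policy="mean")
    assert dm.snp_column("snpA")[1] == pytest.approx(1.0)  # mean of {0, 2}
    with pytest.raises(ValueError, match="missing dosage"):
        io.read_genotypes(tmp_path / "g.tsv", missing_policy="fail")


def test_non_numeric_cell_reports_coordinates(tmp_path):
    (tmp_path / "e.tsv").write_text("gene_id\ts1\ts2\ngA\t1.0\toops\n")
    with pytest.raises(ValueError, match="oops.*row 2.*'s2'"):
        io.read_expression(tmp_path / "e.tsv")


def test_low_maf_and_monomorphic_snps_dropped(tmp_path):
    samples = [f"s{i}" for i in range(10)]
    values = np.zeros((10, 3))
    values[:, 0] = [0, 1, 2, 1, 0, 1, 2, 1, 0, 1]  # common
    values[0, 1] = 1.0  # MAF 0.05 < 0.10
    # column 2 monomorphic
    dm = DosageMatrix(samples, ["common", "rare", "mono"], values)
    pheno = PhenotypeVector(samples, np.arange(10.0))
    expr = __import__("triefdr").ExpressionMatrix(samples, ["g"], np.arange(10.0)[:, None])
    p = write_trio(tmp_path, dm, expr, pheno)
    d2, _, _, _ = io.load_dataset(p["genotypes"], p["expression"], p["phenotype"],
                                  maf_min=0.10)
    assert d2.snp_ids == ["common"]


def test_vcf_dosages_with_missing_call(tmp_path):
    vcf = tmp_path / "toy.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\n"
        "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1|1\n"
        "1\t200\trs2\tA\tC\t.\t.\t.\tGT\t./.\t0/1\t0/0\n"
    )
    dm = io.read_vcf_dosages(vcf, missing_policy="mean")
    assert dm.sample_ids == ["A", "B", "C"]
    np.testing.assert_allclose(dm.snp_column("rs1"), [0, 1, 2])
    np.testing.assert_allclose(dm.snp_column("rs2"), [0.5, 1, 0])  # mean of {1, 0}


def test_results_round_trip(tmp_path, worked_pools):
    obs, _, pool = worked_pools
    table = efdr_qvalues(obs, pool, meta={"seed": 3})
    out = tmp_path / "results.tsv"
    io.write_results(table, out)
    back = io.read_results(out)
    pd.testing.assert_frame_equal(
        back.table, table.table.reset_index(drop=True), check_dtype=False
    )
    np.testing.assert_allclose(back.table["efdr"], table.table["efdr"], atol=0)
    assert back.meta["lambda"] == 0.5 and back.meta["seed"] == 3
    assert back.meta["pi0_hat"] == pytest.approx(table.meta["pi0_hat"])


def test_empty_results_file_has_header_only(tmp_path):
    empty = FdrTable(pd.DataFrame(columns=["snp_id", "genes", "p_obs",
                                           "naive_q", "efdr", "q_efdr"]),
                     {"m": 0})
    out = tmp_path / "empty.tsv"
    io.write_results(empty, out)
    lines = [l for l in out.read_text().splitlines() if not l.startswith("#")]
    assert lines == ["snp_id\tgenes\tp_obs\tnaive_q\tefdr\tq_efdr"]
    assert len(io.read_results(out)) == 0


def test_null_pool_round_trip_with_empty_replicates(tmp_path):
    pool = NullPool(np.array([0.1, 0.5, 0.9]), np.array([2, 0, 1]), n=3, seed=9)
    out = tmp_path / "pool.tsv"
    io.write_null_pool(pool, out)
    back = io.read_null_pool(out)
    np.testing.assert_allclose(back.pooled_pvalues, pool.pooled_pvalues)
    np.testing.assert_array_equal(back.per_replicate_counts, pool.per_replicate_counts)
    assert back.n == 3 and back.seed == 9


def test_thresholds_validation():
    with pytest.raises(ValueError):
        Thresholds(p_gene_phenotype=1.5)
    with pytest.raises(ValueError):
        Thresholds(min_gene_count=0)
    with pytest.raises(ValueError):
        Thresholds(maf_min=0.6)


def test_duplicate_ids_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        DosageMatrix(["a", "a"], ["s"], np.zeros((2, 1)))
    with pytest.raises(ValueError, match="duplicate"):
        EqtlMap.from_tuples([("s", "g", 0.1), ("s", "g", 0.2)])
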