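# triefdr

Empirical false discovery rates for eQTL-informed integrative SNP
prioritization (the "triangle" method).

## The problem

A common way to prioritize GWAS variants is to route them through gene
expression: keep the genes whose expression associates with the phenotype
(p < p<sub>gene-phenotype</sub>), keep the SNPs that are eQTLs of those
genes (p < p<sub>SNP-gene</sub>), and test the surviving SNPs against the
phenotype. This three-arm filter — genotype, expression, phenotype — is the
triangle method.

Assessing the significance of the prioritized SNPs with an ordinary
(Storey-style) FDR is wrong: the selection steps condition on correlation
with the phenotype, so the null distribution of the surviving SNPs'
p-values is *not* uniform — it is enriched near zero, and the naive FDR
flags "significant" SNPs even for a phenotype that is pure noise.

`triefdr` quantifies significance correctly with a permutation-based
**empirical FDR**. The phenotype (with covariates relabeled in sync) is
permuted n times (default 1000); the *identical* filter chain is re-run on
each permuted phenotype against the *fixed* genotype/expression data —
preserving the gene–gene and SNP–SNP correlation structure and the eQTL
map; and the pooled p-values (M₀ = Σ m₀,ₛ of them) form the empirical
null. For each observed p-value t,

    eFDR(t) = [#{p_sim ≤ t}/M₀] / [#{p_obs ≤ t}/m] · π̂₀,

    π̂₀ = [#{p_obs > λ}/m] / [#{p_sim > λ}/M₀],   λ = 0.5,

with π̂₀ clamped to (0, 1] (or fixed at 1 for a conservative bound), and
q-values q̂(t) = min over observed p ≥ t of eFDR(p), capped at 1. When the
null really is uniform this reduces to the classical Storey estimate.

## Worked example

```python
from triefdr import Scenario, simulate_dataset, TriangleModel

# synthetic study: 200 samples, 3000 SNPs in LD blocks, 300 genes,
# 3 causal genes mediating 60% of phenotype variance via their eQTLs
sc = Scenario(phenotype_r2=0.6, n_causal_genes=3, eqtl_effect=2.0, seed=42)
dosages, expr, pheno, truth = simulate_dataset(sc)

model = TriangleModel(dosages, expr, pheno)   # eQTL scan runs once, here
res = model.fit(n_permutations=200, seed=0)
print(res.summary())
```

```
Triangle empirical-FDR results
==============================
samples                 200
genes / SNPs            300 / 3000
eQTL map records        785
genes selected          32 (p < 0.05)
SNPs prioritized (m)    77
permutations (n)        200
null pool size (M0)     7570
lambda / pi0_hat        0.5 / 0.8292
SNPs at q_efdr <= 0.15  19

 snp_id genes     p_obs   naive_q     efdr   q_efdr
rs02716 G0199 1.524e-08 1.174e-06        0        0
rs02717 G0199  1.65e-07 6.351e-06        0        0
rs02189 G0197 1.132e-06 2.474e-05        0        0
...
```

77 SNPs survive the triangle filter (`m`); the 200 permutation replicates
contributed 7570 null p-values (`M0`). An `efdr` of 0 means no permutation
replicate ever produced a p-value that small; `naive_q` is the uniform-null
Storey comparator, which overstates significance whenever the null pool is
enriched near zero. The top SNPs here are the planted eQTLs of the causal
genes (`truth.signal_snps`) and their LD-block neighbours.

The same pipeline is scriptable:

```sh
triefdr simulate --out-dir study --seed 42
triefdr run-all --genotypes study/genotypes.tsv \
    --expression study/expression.tsv --phenotype study/phenotype.tsv \
    --n-permutations 200 --seed 0 --out-dir run
```

which writes the eQTL map, observed p-values, null pool, the per-SNP FDR
table (`results.tsv`) and QQ-plot coordinate files. `triangle`, `null` and
`efdr` run the stages separately; `triefdr efdr` estimates the empirical
FDR for any observed/null p-value files regardless of how they were made.

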