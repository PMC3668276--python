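# Methods

## The triangle filter

Three mass univariate association scans are chained with strict (`<`)
p-value thresholds:

1. **gene–phenotype**: simple linear regression of the phenotype on each
   gene's expression; keep genes with p < p_gene_phenotype (default 0.05).
2. **SNP–gene**: keep SNPs that appear in the eQTL map with
   p < p_snp_gene (default 1e-4) for at least `min_gene_count` selected
   genes (default 1; larger values give the hub-eQTL variant that demands
   a SNP regulate several phenotype-associated genes).
3. **SNP–phenotype**: regress the phenotype on each surviving SNP's
   dosage; keep p < p_snp_phenotype (default 1.0, i.e. no final-arm
   filtering — the final arm then only *scores* the SNPs).

A SNP supported by several genes is tested against the phenotype once and
contributes one p-value; `m` is the number of SNPs in the observed result.
The default p_snp_phenotype = 1.0 is applied identically to the observed
and permuted runs, so the symmetry the null construction requires holds by
construction; any other value is likewise shared by both arms.

The eQTL map is the fixed "genetic machinery": either a supplied
SNP/gene/p-value export (treated as authoritative) or an exhaustive
expression-on-dosage scan computed **once** per dataset. It does not
involve the phenotype and is never recomputed inside the permutation loop
— this is both a correctness requirement (the null must share the observed
machinery) and the reason a 1000-permutation run costs roughly a thousand
gene-phenotype scans, not a thousand eQTL scans.

### Association engine

All arms use the same vectorized simple-regression kernel: per-feature
slope from centered cross-products, two-sided p from the t distribution
with n − 2 degrees of freedom. Covariates are handled by residualizing the
response *and* every predictor on the covariates plus intercept and
testing with n − 2 − c degrees of freedom, which is equivalent to the full
multiple-regression slope test (Frisch–Waugh–Lovell). A constant predictor
column gets slope 0 and p = 1 with a warning rather than an error, so a
permutation loop survives degenerate columns. P-values are floored at the
smallest positive double — the containers require p ∈ (0, 1] — so a
numerically perfect fit reports ~5e-324, not 0.

## Permutation null

Only the phenotype is ever permuted; covariate rows move with it (the
(y, covariates) pairs never decouple). Genotypes and expression stay
fixed, so within each replicate the gene–gene and SNP–SNP correlation
matrices equal the observed ones exactly — the feature of the data that
makes the selected SNPs' null p-values non-uniform is preserved.

Each replicate s draws its permutation from an independent substream
(`SeedSequence(seed, spawn_key=(s,))`), so results are identical whatever
order replicates run in. Permutations are sampled with replacement from
the permutation group and the identity is not excluded; with n = 1000 its
expected impact is negligible and excluding it would bias the null. A
replicate whose cascade empties contributes m₀,ₛ = 0 and no p-values.

## Empirical FDR

With observed p-values {p_obs} (size m) and pooled null p-values {p_sim}
(size M₀ = Σ m₀,ₛ):

- π̂₀ = [#{p_obs > λ}/m] / [#{p_sim > λ}/M₀], λ = 0.5. Clamped to (0, 1]:
  values above 1 are set to 1; a zero or negative ratio (every observed
  p ≤ λ) is floored at 1e-8 with a warning — the floor's exact value is
  immaterial since it only arises when essentially everything is called.
  If no simulated p exceeds λ, π̂₀ = 1 with a warning. π̂₀ is estimated
  once from the full pools, not per cutoff. `conservative=True` fixes
  π̂₀ = 1 (an upper bound on the eFDR).
- eFDR(t) = [#{p_sim ≤ t}/M₀] / [#{p_obs ≤ t}/m] · π̂₀, evaluated at every
  observed p-value t, capped at 1. Counting is inclusive (≤), deliberately
  asymmetric with the strict (<) filter thresholds. If no simulated value
  reaches t, eFDR(t) = 0. Tied observed p-values share one t and hence one
  eFDR.
- q̂(t) = min over observed p ≥ t of eFDR(p) (running minimum from the
  largest cutoff down), which makes q̂ nondecreasing in p; the minimum
  ranges over observed p-values only, the only points where eFDR is
  evaluated.
- M₀ = 0 (no permutation ever selected a SNP) is a degenerate null: all
  eFDR are set to 0 with a prominent warning rather than failing, since an
  empty null pool genuinely means the observed selection is unlike
  anything the permutations produced — but the estimate carries no
  information and the warning says so.

The naive comparator is the uniform-null Storey estimate
FDR(t) = π₀ · m · t / #{p_obs ≤ t} (default π₀ = 1), monotonized and
capped identically. When {p_sim} is uniform the two coincide (verified
against a 10⁶-point uniform grid to < 0.01); the empirical estimator is a
strict generalization.

QQ coordinates use expected quantile i/(m+1) for rank i, both axes
−log10-transformed.

## Synthetic studies

The generator produces data with exactly the structure the method's
correctness argument leans on:

- **Genotypes**: haplotype-copying LD blocks. Each SNP draws its allele
  frequency from `maf_range` (default 0.1–0.5); within a block (default 10
  SNPs) each haplotype allele copies the previous SNP's allele with
  probability `ld_r` (default 0.8), else is drawn fresh. Dosages are valid
  {0, 1, 2} by construction; adjacent within-block correlation ≈ ld_r;
  blocks are independent.
- **Expression**: low-rank factor structure plus planted eQTLs,
  `expr_g = β·dosage + loadings_g·factors + noise`, with loadings and
  noise scaled so the non-genetic variance is 1 (two genes loading l on a
  shared factor correlate at ≈ l²). A fraction `eqtl_fraction` (default
  0.3) of genes carries one eQTL of effect `eqtl_effect` (default 1 per
  dosage unit — against unit non-genetic variance this puts the typical
  SNP-gene r² near 0.2–0.3, i.e. a strong cis-eQTL).
- **Phenotype**: y = Σ γ_g · expr_g + ε over `n_causal_genes` causal
  genes, with γ of equal magnitude and random sign (balanced mediation)
  and ε scaled so the causal genes explain `phenotype_r2` of the variance.
  `phenotype_r2 = 0` is the pure-null study: y is standard normal,
  independent of everything, and no gene is causal. When the phenotype is
  mediated, causal genes are drawn from the genes carrying a planted eQTL
  when enough exist — the genotype → expression → phenotype path is the
  structure the triangle targets; without it there would be no signal SNPs
  to recover.

Truth labels record the planted (SNP, gene) pairs, the causal genes, and
the **signal SNPs** (eQTLs of causal genes). Because signal SNPs sit
inside LD blocks, their block-mates are correlated with them and therefore
genuinely phenotype-associated; the calibration harness counts a
discovery as true if its block contains a signal SNP, and false only if
it is independent of every planted signal.

What the generator does *not* emulate: realistic human LD maps and allele
spectra, population structure, cis-window geometry, batch effects,
trans-eQTL networks, non-Gaussian expression. Passing tests show the
estimator does what its definition says under the assumed structure; they
do not certify behaviour under confounding the generator omits (under
expression-side confounding the estimator is expected to be conservative,
since extra noise genes inflate the null pool more than the observed set).

## Study sizes and experiments

The repeated-study experiments in `triefdr.experiments` (also driven by
`scripts/acceptance.py`) use a desk-scale design — 200 samples, 3000 SNPs,
300 genes, 200 permutations — a ~30× reduction of a cell-line eQTL study
that preserves every structural feature (LD, factor correlation,
mediation) while a full experiment of 20 independent studies runs in
seconds per study.

- **Pure-null experiment** (phenotype_r2 = 0, 20 draws): every discovery
  is spurious. The naive Storey q < 0.05 flags at least one SNP in a
  sizable fraction of draws (~30% at these sizes) — the selection-bias
  pathology — while empirical-FDR discoveries average ≲ 0.1 per draw.
- **Calibration experiment** (phenotype_r2 = 0.4, 10 causal genes, 20
  replicates): realized false-discovery proportion among SNPs called at
  q̂ ≤ 0.15, averaged over replicates that call at least one SNP (the
  proportion is undefined when nothing is called). With only a handful of
  calls per replicate this quantity is noisy; across many seeds it
  averages near the nominal 0.15 (individual 20-replicate experiments
  ranged roughly 0.08–0.42 in our runs), consistent with an approximately
  unbiased estimator observed through small-sample noise.
- **Power experiment** (phenotype_r2 = 0.8 concentrated in 3 causal
  genes, eqtl_effect = 3): effects are set so every planted signal SNP's
  marginal SNP-phenotype p is well below 1e-4; all signal SNPs are then
  recovered at q̂ < 0.15 and rank ahead of the other prioritized SNPs.

## Numerical conventions and edge cases

- Strict `<` at every filter threshold (ties at a cutoff excluded);
  inclusive `≤` in every FDR count.
- Missing genotype dosages: per-SNP mean imputation at load time (keeps
  the regression design dense); policy `fail` raises instead. SNPs with
  folded MAF below `maf_min` (default 0.05) or monomorphic are dropped at
  load time, after sample alignment.
- Sample alignment: the phenotype file defines the canonical sample
  order; genotype and expression are reindexed to the intersection.
- File round trips are bit-exact: writers use 17-significant-digit
  formatting and readers parse through numpy's correctly-rounded float
  conversion.
- Determinism: every random draw descends from a single seed; the same
  configuration byte-reproduces the results file.

## Known limitations

- Quantitative phenotypes only (no binary/ordinal models).
- One molecular layer (expression); protein/microRNA layers would slot in
  as additional filter arms but are not implemented.
- π̂₀ uses a single λ (no spline/grid smoothing); no local-FDR variant.
- The permutation null assumes exchangeable samples; kinship or structure
  among samples would require restricted permutations, which are not
  provided.
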