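"""Repeated-study experiments: false-discovery behaviour of the naive and
empirical FDR across many simulated datasets.

These harnesses are the package's calibration suite. Each experiment draws
independent synthetic studies from a :class:`~triefdr.simulate.Scenario`,
runs the full pipeline (eQTL scan once per study, observed triangle,
permutation null, eFDR), and reports discovery counts against the planted
truth. Discoveries are judged at the LD-block level: a called SNP in the
same block as a planted signal SNP is correlated with it, hence genuinely
phenotype-associated, and is not counted as a false discovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assoc import compute_eqtl_map
from .datatypes import Thresholds
from .model import TriangleModel
from .simulate import Scenario, expand_signal_to_blocks, simulate_dataset

__all__ = [
    "NullExperimentResult",
    "CalibrationResult",
    "PowerResult",
    "pure_null_experiment",
    "calibration_experiment",
    "power_experiment",
]


def _fit_one(sc: Scenario, th: Thresholds, n_permutations: int, seed: int):
    dosages, expr, pheno, truth = simulate_dataset(sc)
    eqtl_map = compute_eqtl_map(dosages, expr, th.p_snp_gene)
    model = TriangleModel(dosages, expr, pheno, eqtl_map, th)
    res = model.fit(n_permutations=n_permutations, seed=seed)
    return dosages, truth, res


@dataclass
class NullExperimentResult:
    """Per-draw discovery counts under a phenotype with no genetic signal."""

    naive_discoveries: np.ndarray  # SNPs at naive Storey q < alpha, per draw
    efdr_discoveries: np.ndarray  # SNPs at q_efdr < alpha, per draw
    alpha: float
    m_per_draw: np.ndarray = field(default=None)

    @property
    def n_draws(self) -> int:
        return len(self.naive_discoveries)

    @property
    def frac_draws_with_naive_hit(self) -> float:
        return float(np.mean(self.naive_discoveries >= 1))

    @property
    def mean_efdr_discoveries(self) -> float:
        return float(np.mean(self.efdr_discoveries))


def pure_null_experiment(
    scenario: Scenario | None = None,
    n_draws: int = 20,
    n_permutations: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    thresholds: Thresholds | None = None,
) -> NullExperimentResult:
    """Every discovery here is spurious: the phenotype is pure noise.

    Exposes the failure mode of the uniform-null comparator: after the
    triangle's selection steps, p-values of the surviving SNPs are enriched
    near zero even under the global null, so naive q-values routinely flag
    SNPs. The empirical FDR, whose null pool has the same enrichment,
    should flag (almost) none.
    """
    sc = (scenario or Scenario()).with_(phenotype_r2=0.0)
    th = thresholds or Thresholds()
    naive, efdr, ms = [], [], []
    for d in range(n_draws):
        sub = int(np.random.SeedSequence(seed, spawn_key=(d,)).generate_state(1)[0] % (2**31))
        _, _, res = _fit_one(sc.with_(seed=sub), th, n_permutations, seed=sub)
        t = res.table
        naive.append(int((t["naive_q"] < alpha).sum()))
        efdr.append(int((t["q_efdr"] < alpha).sum()))
        ms.append(res.m)
    return NullExperimentResult(np.array(naive), np.array(efdr), alpha, np.array(ms))


@dataclass
class CalibrationResult:
    """Realized false-discovery proportions at a target q-value cutoff."""

    fdp: np.ndarray  # per-replicate realized FDP among calls at q <= q_max
    n_called: np.ndarray
    n_true: np.ndarray
    q_max: float

    @property
    def mean_fdp(self) -> float:
        """Average FDP over replicates that called at least one SNP.

        The proportion of false calls is undefined when nothing is called,
        so empty replicates are excluded rather than counted as zeros.
        """
        informative = self.fdp[self.n_called > 0]
        return float(np.mean(informative)) if len(informative) else 0.0

    @property
    def pooled_fdp(self) -> float:
        """Total false calls over total calls, pooled across replicates."""
        called = int(self.n_called.sum())
        return float((called - self.n_true.sum()) / called) if called else 0.0


def calibration_experiment(
    scenario: Scenario | None = None,
    n_replicates: int = 20,
    n_permutations: int = 200,
    q_max: float = 0.15,
    seed: int = 0,
    thresholds: Thresholds | None = None,
) -> CalibrationResult:
    """Does calling SNPs at q_efdr <= q_max realize about q_max FDP?

    A replicate with no calls contributes FDP 0 (no discoveries, no false
    ones). Truth is block-expanded: LD mates of planted signal SNPs count
    as true.
    """
    sc = scenario or Scenario(phenotype_r2=0.4, n_causal_genes=10, eqtl_fraction=0.3)
    th = thresholds or Thresholds()
    fdp, n_called, n_true = [], [], []
    for d in range(n_replicates):
        sub = int(np.random.SeedSequence(seed, spawn_key=(d,)).generate_state(1)[0] % (2**31))
        dosages, truth, res = _fit_one(sc.with_(seed=sub), th, n_permutations, seed=sub)
        non_null = expand_signal_to_blocks(dosages, truth, sc)
        called = res.table.loc[res.table["q_efdr"] <= q_max, "snp_id"]
        false = sum(1 for s in called if s not in non_null)
        fdp.append(false / len(called) if len(called) else 0.0)
        n_called.append(len(called))
        n_true.append(len(called) - false)
    return CalibrationResult(np.array(fdp), np.array(n_called), np.array(n_true), q_max)


@dataclass
class PowerResult:
    """Recovery of planted signal SNPs at a target q-value cutoff."""

    n_signal: int
    n_recovered: int
    median_signal_rank: float
    median_other_rank: float
    min_signal_marginal_p: float
    max_signal_marginal_p: float

    @property
    def recovery_fraction(self) -> float:
        return self.n_recovered / self.n_signal if self.n_signal else float("nan")


def power_experiment(
    scenario: Scenario | None = None,
    n_permutations: int = 200,
    q_max: float = 0.15,
    seed: int = 0,
    thresholds: Thresholds | None = None,
    n_draws: int = 5,
) -> PowerResult:
    """Strong-effect mediated scenario: planted signal SNPs should be
    recovered at q <= q_max and rank ahead of the other prioritized SNPs.

    The default scenario concentrates the heritable variance in few causal
    genes with strong eQTL effects so each signal SNP's marginal
    SNP-phenotype association is itself strong (p well below 1e-4).
    """
    sc = scenario or Scenario(
        phenotype_r2=0.8, n_causal_genes=3, eqtl_fraction=0.3, eqtl_effect=3.0
    )
    th = thresholds or Thresholds()
    n_signal = n_rec = 0
    sig_ranks, other_ranks, marg_p = [], [], []
    for d in range(n_draws):
        sub = int(np.random.SeedSequence(seed, spawn_key=(d,)).generate_state(1)[0] % (2**31))
        dosages, truth, res = _fit_one(sc.with_(seed=sub), th, n_permutations, seed=sub)
        t = res.table.reset_index(drop=True)
        qmap = dict(zip(t["snp_id"], t["q_efdr"]))
        n_signal += len(truth.signal_snps)
        n_rec += sum(1 for s in truth.signal_snps if qmap.get(s, np.inf) < q_max)
        for rank, snp in enumerate(t["snp_id"]):
            (sig_ranks if snp in truth.signal_snps else other_ranks).append(rank)
        from .assoc import mass_simple_regression

        snps = sorted(truth.signal_snps)
        if snps:
            marg = mass_simple_regression(dosages.snp_columns(snps), res.model.phenotype.y)
            marg_p.extend(marg.pvalue.tolist())
    return PowerResult(
        n_signal=n_signal,
        n_recovered=n_rec,
        median_signal_rank=float(np.median(sig_ranks)) if sig_ranks else float("nan"),
        median_other_rank=float(np.median(other_ranks)) if other_ranks else float("nan"),
        min_signal_marginal_p=float(np.min(marg_p)) if marg_p else float("nan"),
        max_signal_marginal_p=float(np.max(marg_p)) if marg_p else float("nan"),
    )
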