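"""Empirical FDR and q-values against a permutation null.

Classical Storey q-values assume the null p-values are Uniform(0, 1). After
the triangle's selection steps that assumption fails — the selected SNPs'
null p-values are enriched near zero because selection conditions on
correlation with the (possibly permuted) phenotype. The estimator here
replaces the uniform null with the pooled permutation distribution:

    eFDR(t) = [#{p_sim <= t} / M0] / [#{p_obs <= t} / m] * pi0

with pi0 estimated from the lambda-tails of both pools,

    pi0 = [#{p_obs > lambda} / m] / [#{p_sim > lambda} / M0],

clamped to (0, 1] (or fixed at 1 for a conservative bound). q-values are
the running minimum of eFDR over observed cutoffs >= t, which makes them
nondecreasing in the p-value; everything is capped at 1.

Counting is inclusive (``<= t``) with t ranging over the observed p-values
themselves. Note the deliberate asymmetry with the strict ``<`` thresholds
of the triangle filters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .permnull import NullPool
from .triangle import TriangleResult

__all__ = [
    "FdrTable",
    "pi0_hat",
    "empirical_fdr_at",
    "efdr_qvalues",
    "storey_naive_qvalues",
    "qq_coordinates",
]

_PI0_FLOOR = 1e-8


@dataclass
class FdrTable:
    """Per-SNP FDR estimates plus the run metadata needed to reproduce them.

    ``table`` columns: snp_id, genes (comma-joined supporting genes), p_obs,
    naive_q (uniform-null Storey comparator), efdr, q_efdr; rows sorted by
    p_obs. ``meta`` records lambda, pi0_hat, m, M0, n permutations,
    thresholds, seed, conservative flag.
    """

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)


def _as_parray(p: Iterable[float], what: str) -> np.ndarray:
    arr = np.asarray(list(p) if not isinstance(p, np.ndarray) else p, dtype=float).ravel()
    if len(arr) and not ((arr > 0).all() and (arr <= 1).all()):
        raise ValueError(f"{what} p-values must lie in (0, 1]")
    return arr


def pi0_hat(obs_p: Iterable[float], sim_p: Iterable[float], lam: float = 0.5) -> float:
    """Proportion of observed SNPs that are null, from the lambda-tails.

    The numerator and denominator are the fractions of observed and
    simulated p-values exceeding lambda; their ratio estimates P(null)
    because beyond lambda the observed distribution should look like the
    null one. Clamped to (0, 1].
    """
    obs = _as_parray(obs_p, "observed")
    sim = _as_parray(sim_p, "simulated")
    if len(obs) == 0 or len(sim) == 0:
        raise ValueError("pi0_hat requires non-empty observed and simulated pools")
    if not (0.0 < lam < 1.0):
        raise ValueError(f"lambda must lie in (0, 1), got {lam}")
    sim_tail = np.count_nonzero(sim > lam) / len(sim)
    if sim_tail == 0:
        warnings.warn(
            f"no simulated p-value exceeds lambda={lam}; pi0 set to 1", RuntimeWarning
        )
        return 1.0
    obs_tail = np.count_nonzero(obs > lam) / len(obs)
    pi0 = obs_tail / sim_tail
    if pi0 <= 0:
        warnings.warn(
            f"all observed p-values are <= lambda={lam}; pi0 clamped to {_PI0_FLOOR}",
            RuntimeWarning,
        )
        return _PI0_FLOOR
    return float(min(pi0, 1.0))


def empirical_fdr_at(
    t: float, obs_p: Iterable[float], sim_p: Iterable[float], pi0: float = 1.0
) -> float:
    """eFDR of rejecting all observed p-values <= t, capped at 1.

    ``t`` is always one of the observed p-values in practice, so the
    denominator count is positive. If no simulated p-value reaches t the
    estimate is 0: the permutation null never produced a value that small.
    """
    if not (0.0 <= t <= 1.0):
        raise ValueError(f"t must lie in [0, 1], got {t}")
    obs = _as_parray(obs_p, "observed")
    sim = _as_parray(sim_p, "simulated")
    if len(obs) == 0 or len(sim) == 0:
        raise ValueError("empirical_fdr_at requires non-empty pools")
    n_obs = np.count_nonzero(obs <= t)
    if n_obs == 0:
        raise ValueError(f"no observed p-value <= t={t}; eFDR undefined there")
    n_sim = np.count_nonzero(sim <= t)
    if n_sim == 0:
        return 0.0
    efdr = (n_sim / len(sim)) / (n_obs / len(obs)) * pi0
    return float(min(efdr, 1.0))


def _monotone_q(p_sorted: np.ndarray, fdr_sorted: np.ndarray) -> np.ndarray:
    """q(t) = min over observed p >= t of FDR(p)."""
    return np.minimum.accumulate(fdr_sorted[::-1])[::-1]


def storey_naive_qvalues(obs_p: Iterable[float], pi0: float = 1.0) -> np.ndarray:
    """Uniform-null Storey q-values — the comparator the eFDR replaces.

    FDR(t) = pi0 * m * t / #{p_obs <= t} at each observed t, monotonized by
    the running minimum over larger cutoffs and capped at 1. Returned in
    the input order.
    """
    obs = _as_parray(obs_p, "observed")
    m = len(obs)
    if m == 0:
        raise ValueError("need at least one observed p-value")
    order = np.argsort(obs, kind="stable")
    p_sorted = obs[order]
    # inclusive count of p <= t at t = each sorted p (ties share the count)
    n_le = np.searchsorted(p_sorted, p_sorted, side="right")
    fdr = np.minimum(pi0 * m * p_sorted / n_le, 1.0)
    q_sorted = _monotone_q(p_sorted, fdr)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def efdr_qvalues(
    obs,
    pool: NullPool,
    lam: float = 0.5,
    conservative: bool = False,
    provenance: Mapping[str, set] | None = None,
    meta: dict | None = None,
) -> FdrTable:
    """Empirical FDR and q-values for every observed SNP.

    ``obs`` is a TriangleResult or a mapping snp_id -> p_obs. Evaluates
    eFDR at each observed p-value, monotonizes into q-values, and fills the
    naive Storey comparator column. With ``conservative=True`` pi0 is fixed
    at 1 (an upper bound on the eFDR).
    """
    if isinstance(obs, TriangleResult):
        if provenance is None:
            provenance = obs.provenance
        obs_map = obs.snp_pvalues
    else:
        obs_map = dict(obs)
    provenance = provenance or {}

    snp_ids = np.asarray(list(obs_map.keys()), dtype=object)
    obs_p = _as_parray(list(obs_map.values()), "observed")
    meta = dict(meta or {})
    meta.update({"lambda": lam, "conservative": conservative, "m": len(obs_p),
                 "M0": pool.M0, "n_permutations": pool.n})

    columns = ["snp_id", "genes", "p_obs", "naive_q", "efdr", "q_efdr"]
    if len(obs_p) == 0:
        meta["pi0_hat"] = np.nan
        return FdrTable(pd.DataFrame(columns=columns), meta)

    order = np.argsort(obs_p, kind="stable")
    p_sorted = obs_p[order]
    m = len(obs_p)

    sim = np.sort(pool.pooled_pvalues)
    M0 = pool.M0
    if M0 == 0:
        warnings.warn(
            "degenerate permutation null: no replicate ever selected a SNP "
            "(M0 = 0); eFDR set to 0 everywhere — interpret with caution",
            RuntimeWarning,
        )
        pi0 = 1.0
        efdr_sorted = np.zeros(m)
    else:
        pi0 = 1.0 if conservative else pi0_hat(obs_p, sim, lam)
        n_sim_le = np.searchsorted(sim, p_sorted, side="right")
        n_obs_le = np.searchsorted(p_sorted, p_sorted, side="right")
        efdr_sorted = np.minimum((n_sim_le / M0) / (n_obs_le / m) * pi0, 1.0)
    meta["pi0_hat"] = pi0

    q_sorted = _monotone_q(p_sorted, efdr_sorted)
    naive_q_sorted = storey_naive_qvalues(p_sorted)

    sorted_ids = snp_ids[order]
    genes = [",".join(sorted(provenance.get(s, set()))) for s in sorted_ids]
    table = pd.DataFrame(
        {
            "snp_id": sorted_ids,
            "genes": genes,
            "p_obs": p_sorted,
            "naive_q": naive_q_sorted,
            "efdr": efdr_sorted,
            "q_efdr": q_sorted,
        }
    )
    return FdrTable(table, meta)


def qq_coordinates(p: Iterable[float]) -> tuple[np.ndarray, np.ndarray]:
    """Expected vs observed quantiles on the -log10 scale for a QQ plot.

    Rank i of m gets expected quantile i/(m+1); observed p-values are
    sorted ascending. Both are returned -log10-transformed, paired by rank.
    """
    obs = np.asarray(list(p) if not isinstance(p, np.ndarray) else p, dtype=float).ravel()
    if len(obs) == 0:
        raise ValueError("need at least one p-value")
    if not ((obs > 0).all() and (obs <= 1).all()):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(obs)
    expected = np.arange(1, m + 1) / (m + 1)
    return -np.log10(expected), -np.log10(np.sort(obs))
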