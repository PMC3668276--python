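"""Empirical FDR estimator: worked counting examples, a brute-force count
oracle, the uniform-null degeneration, and property-based invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triefdr import (
    NullPool,
    efdr_qvalues,
    empirical_fdr_at,
    pi0_hat,
    qq_coordinates,
    storey_naive_qvalues,
)


def brute_force_efdr(obs_p, sim_p, lam=0.5, conservative=False):
    """Direct double-loop counting of the eFDR and q-value definitions."""
    obs = np.asarray(sorted(obs_p))
    sim = np.asarray(sim_p)
    m, M0 = len(obs), len(sim)
    if conservative:
        pi0 = 1.0
    else:
        num = sum(1 for p in obs if p > lam) / m
        den = sum(1 for p in sim if p > lam) / M0
        pi0 = 1.0 if den == 0 else min(max(num / den, 1e-8), 1.0)
    efdr = []
    for t in obs:
        n_sim = sum(1 for p in sim if p <= t)
        n_obs = sum(1 for p in obs if p <= t)
        e = 0.0 if n_sim == 0 else min((n_sim / M0) / (n_obs / m) * pi0, 1.0)
        efdr.append(e)
    q = [min(e for tt, e in zip(obs, efdr) if tt >= t) for t in obs]
    return obs, np.array(efdr), np.array(q), pi0


def as_pool(sim):
    sim = np.asarray(sim, dtype=float)
    return NullPool(sim, np.array([len(sim)]), n=1, seed=0)


class TestWorkedExample:
    """obs = {.01, .2, .6, .9}, sim = {.05, .3, .55, .7, .95}, lambda = .5."""

    obs = [0.01, 0.2, 0.6, 0.9]
    sim = [0.05, 0.3, 0.55, 0.7, 0.95]

    def test_pi0(self):
        assert pi0_hat(self.obs, self.sim, 0.5) == pytest.approx((2 / 4) / (3 / 5))

    def test_pi0_identical_pools_is_one(self):
        assert pi0_hat(self.obs, self.obs, 0.5) == pytest.approx(1.0)

    def test_efdr_at_point(self):
        pi0 = pi0_hat(self.obs, self.sim, 0.5)
        assert empirical_fdr_at(0.2, self.obs, self.sim, pi0) == pytest.approx(1 / 3)

    def test_efdr_conservative_bound(self):
        assert empirical_fdr_at(0.2, self.obs, self.sim, 1.0) == pytest.approx(0.4)

    def test_zero_when_null_never_reaches_t(self):
        assert empirical_fdr_at(0.01, self.obs, self.sim, 1.0) == 0.0

    def test_full_table(self):
        tab = efdr_qvalues({f"s{i}": p for i, p in enumerate(self.obs)}, as_pool(self.sim))
        np.testing.assert_allclose(tab.table["p_obs"], sorted(self.obs))
        np.testing.assert_allclose(tab.table["efdr"], [0, 1 / 3, 2 / 3, 2 / 3])
        np.testing.assert_allclose(tab.table["q_efdr"], [0, 1 / 3, 2 / 3, 2 / 3])
        assert tab.meta["pi0_hat"] == pytest.approx(5 / 6)


def test_q_monotonization_hand_example():
    """eFDR (0.3, 0.1, 0.4) at sorted p -> q (0.1, 0.1, 0.4)."""
    from triefdr.efdr import _monotone_q

    q = _monotone_q(np.array([0.01, 0.05, 0.2]), np.array([0.3, 0.1, 0.4]))
    np.testing.assert_allclose(q, [0.1, 0.1, 0.4])


def test_matches_count_oracle_random_pools(rng):
    for _ in range(50):
        m = int(rng.integers(1, 60))
        M0 = int(rng.integers(1, 100))
        obs = rng.uniform(1e-6, 1.0, m)
        sim = rng.uniform(1e-6, 1.0, M0)
        conservative = bool(rng.integers(2))
        tab = efdr_qvalues({f"s{i}": p for i, p in enumerate(obs)},
                           as_pool(sim), conservative=conservative)
        _, efdr, q, pi0 = brute_force_efdr(obs, sim, conservative=conservative)
        np.testing.assert_array_equal(tab.table["efdr"].to_numpy(), efdr)
        np.testing.assert_array_equal(tab.table["q_efdr"].to_numpy(), q)
        assert tab.meta["pi0_hat"] == pi0


def test_uniform_null_reduces_to_storey(rng):
    """With a uniform simulated pool the eFDR degenerates to the classical
    Storey estimate pi0 * t / (#{p_obs <= t}/m)."""
    M0 = 100_000
    sim = (np.arange(1, M0 + 1) - 0.5) / M0
    obs = np.sort(rng.uniform(0.001, 1.0, 40))
    pi0 = pi0_hat(obs, sim, 0.5)
    m = len(obs)
    for t in obs:
        efdr = empirical_fdr_at(t, obs, sim, pi0)
        storey = min(pi0 * t / (np.count_nonzero(obs <= t) / m), 1.0)
        assert abs(efdr - storey) < 0.01


def test_storey_naive_single_p_equals_p():
    assert storey_naive_qvalues([0.03])[0] == pytest.approx(0.03)


def test_storey_naive_hand_example():
    q = storey_naive_qvalues([0.01, 0.2, 0.6, 0.9])
    np.testing.assert_allclose(q, [0.04, 0.4, 0.8, 0.9])


def test_storey_naive_uniform_grid_all_one():
    m = 10
    q = storey_naive_qvalues(np.arange(1, m + 1) / m)
    np.testing.assert_allclose(q, np.ones(m))


def test_naive_fdr_pathology_constructible():
    """A null pool concentrated near zero: the uniform-null comparator calls
    a SNP highly significant while the empirical FDR does not."""
    obs = {"a": 0.001, "b": 0.3, "c": 0.7}
    sim = np.concatenate([np.full(600, 0.0005), np.full(400, 0.9)])
    tab = efdr_qvalues(obs, as_pool(sim)).table.set_index("snp_id")
    assert tab.loc["a", "naive_q"] < 0.05
    assert tab.loc["a", "efdr"] > 0.5


def test_degenerate_null_m0_zero_warns():
    pool = NullPool(np.empty(0), np.zeros(3, dtype=int), n=3, seed=0)
    with pytest.warns(RuntimeWarning, match="M0 = 0"):
        tab = efdr_qvalues({"a": 0.01, "b": 0.4}, pool)
    np.testing.assert_array_equal(tab.table["efdr"], 0.0)


def test_scale_invariance_duplicated_pool(worked_pools):
    obs, sim, pool = worked_pools
    doubled = as_pool(np.concatenate([sim, sim]))
    a = efdr_qvalues(obs, pool).table
    b = efdr_qvalues(obs, doubled).table
    np.testing.assert_allclose(a["efdr"], b["efdr"])
    np.testing.assert_allclose(a["q_efdr"], b["q_efdr"])


def test_tied_observed_pvalues_share_q():
    obs = {"a": 0.2, "b": 0.2, "c": 0.8}
    tab = efdr_qvalues(obs, as_pool([0.1, 0.5, 0.9])).table.set_index("snp_id")
    assert tab.loc["a", "efdr"] == tab.loc["b", "efdr"]
    assert tab.loc["a", "q_efdr"] == tab.loc["b", "q_efdr"]


p_values = st.floats(min_value=1e-6, max_value=1.0, allow_nan=False)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    obs=st.lists(p_values, min_size=1, max_size=30),
    sim=st.lists(p_values, min_size=1, max_size=50),
    conservative=st.booleans(),
)
def test_q_monotone_and_bounded(obs, sim, conservative):
    """q_efdr is nondecreasing in p_obs and every FDR quantity is in [0, 1]."""
    tab = efdr_qvalues({f"s{i}": p for i, p in enumerate(obs)},
                       as_pool(sim), conservative=conservative)
    t = tab.table
    assert (np.diff(t["q_efdr"]) >= -1e-15).all()
    for col in ("naive_q", "efdr", "q_efdr"):
        assert ((t[col] >= 0) & (t[col] <= 1)).all()
    assert 0 < tab.meta["pi0_hat"] <= 1


def test_qq_coordinates_hand_example():
    exp, obs = qq_coordinates([0.1, 0.01])
    np.testing.assert_allclose(obs, [2.0, 1.0])
    np.testing.assert_allclose(exp, [-np.log10(1 / 3), -np.log10(2 / 3)])


def test_qq_expected_rank_formula():
    exp, _ = qq_coordinates([0.1, 0.2, 0.3, 0.4])
    np.testing.assert_allclose(10.0 ** (-exp), [0.2, 0.4, 0.6, 0.8])


def test_qq_rejects_zero_pvalue():
    with pytest.raises(ValueError):
        qq_coordinates([0.0, 0.5])
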