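"""Coalescent rates, genealogy simulation and expected spectra.

Expected spectra are checked against three independent oracles: the Kingman
closed form, an exact Markov-chain enumeration over block-size partitions at
small n (implemented here, independent of the package's simulation path),
and msprime's Beta-coalescent simulator at n = 20.
"""

import itertools
import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import beta as beta_fn, comb

from mmcoal import (
    CoalescentModel,
    expected_normalized_sfs,
    kingman_phi,
    merger_rate,
    simulate_genealogy,
)


# ---------------------------------------------------------------------------
# independent oracle: exact expected L_i by enumeration of the block-size
# partition chain (feasible for n <= ~8)


def exact_phi(n, lam):
    """Exact normalized expected SFS for merger rates lam(b, k)."""
    start = tuple([1] * n)
    visits = {start: 1.0}
    expected_L = np.zeros(n - 1)
    # states ordered by decreasing block count so predecessors come first
    frontier = {start}
    by_blocks = {n: {start}}
    for b in range(n, 1, -1):
        for state in sorted(by_blocks.get(b, ())):
            prob = visits.get(state, 0.0)
            if prob == 0.0:
                continue
            rates_k = {k: comb(b, k, exact=True) * lam(b, k)
                       for k in range(2, b + 1)}
            total = sum(rates_k.values())
            hold = prob / total
            for size in state:
                expected_L[size - 1] += hold
            for k, rk in rates_k.items():
                if rk == 0.0:
                    continue
                p_each = (rk / total) / comb(b, k, exact=True)
                for idx in itertools.combinations(range(b), k):
                    merged = sum(state[i] for i in idx)
                    rest = [state[i] for i in range(b) if i not in idx]
                    new = tuple(sorted(rest + [merged]))
                    visits[new] = visits.get(new, 0.0) + prob * p_each
                    by_blocks.setdefault(len(new), set()).add(new)
    return expected_L / expected_L.sum()


def beta_lambda(alpha):
    def lam(b, k):
        return beta_fn(k - alpha, b - k + alpha) / beta_fn(2 - alpha, alpha)
    return lam


def dirac_lambda(psi):
    def lam(b, k):
        return psi ** (k - 2) * (1 - psi) ** (b - k)
    return lam


# ---------------------------------------------------------------------------


class TestMergerRate:
    def test_kingman_pairs_only(self):
        m = CoalescentModel.kingman()
        assert merger_rate(5, 2, m) == 1.0
        assert merger_rate(5, 3, m) == 0.0

    def test_beta_value_matches_numeric_integral(self):
        """lambda_{3,3} at alpha=1.5 vs direct integration of the measure."""
        alpha = 1.5
        val = merger_rate(3, 3, CoalescentModel.beta(alpha))
        dens = lambda x: (x ** (1 - alpha) * (1 - x) ** (alpha - 1)
                          / beta_fn(2 - alpha, alpha))
        num, _ = quad(lambda x: x ** (3 - 2) * (1 - x) ** 0 * dens(x), 0, 1)
        assert val == pytest.approx(0.25, abs=1e-12)
        assert val == pytest.approx(num, rel=1e-8)

    def test_dirac_value(self):
        assert merger_rate(4, 3, CoalescentModel.dirac(0.1)) == pytest.approx(0.09)

    def test_merger_size_bounds(self):
        with pytest.raises(ValueError):
            merger_rate(3, 4, CoalescentModel.kingman())
        with pytest.raises(ValueError):
            merger_rate(3, 1, CoalescentModel.kingman())

    @pytest.mark.parametrize("family,bad", [
        ("beta", 0.9), ("beta", 2.1), ("dirac", 0.0), ("dirac", 1.0001),
        ("exp_growth", -1.0),
    ])
    def test_parameter_ranges(self, family, bad):
        with pytest.raises(ValueError):
            CoalescentModel(family, bad)

    def test_beta_alpha2_is_kingman(self):
        m = CoalescentModel.beta(2.0)
        assert merger_rate(6, 2, m) == 1.0
        assert merger_rate(6, 4, m) == 0.0


class TestSimulateGenealogy:
    def test_pair_tmrca_unit_mean(self):
        times = [simulate_genealogy(2, CoalescentModel.kingman(), seed=s).tmrca
                 for s in range(10_000)]
        se = np.std(times, ddof=1) / math.sqrt(len(times))
        assert abs(np.mean(times) - 1.0) < 3 * se

    def test_winner_take_all_dirac(self):
        g = simulate_genealogy(8, CoalescentModel.dirac(1.0), seed=0)
        assert len(g.event_log) == 1
        assert g.event_log[0][1] == 8
        L = g.branch_lengths_by_class
        assert L[0] > 0 and not L[1:].any()

    def test_class_length_accounting(self):
        g = simulate_genealogy(12, CoalescentModel.beta(1.2), seed=4)
        assert g.total_length == pytest.approx(
            sum(length for _, length in g.branches))
        assert (g.branch_lengths_by_class >= 0).all()
        assert g.tmrca >= g.event_log[0][0]

    def test_rejects_tiny_samples(self):
        with pytest.raises(ValueError):
            simulate_genealogy(1, CoalescentModel.kingman())

    def test_newick_parses_and_preserves_length(self):
        from io import StringIO

        from Bio import Phylo

        g = simulate_genealogy(9, CoalescentModel.beta(1.4), seed=11)
        tree = Phylo.read(StringIO(g.newick()), "newick")
        assert tree.count_terminals() == 9
        assert tree.total_branch_length() == pytest.approx(g.total_length,
                                                           rel=1e-6)

    def test_growth_reduces_to_kingman_at_zero_rate(self):
        a = simulate_genealogy(6, CoalescentModel.exp_growth(0.0), seed=7)
        b = simulate_genealogy(6, CoalescentModel.alg_growth(0.0), seed=7)
        assert a.tmrca == pytest.approx(b.tmrca)

    def test_growth_shortens_genealogies(self):
        """Backwards-shrinking population speeds coalescence."""
        slow = [simulate_genealogy(10, CoalescentModel.exp_growth(0.0), s).tmrca
                for s in range(400)]
        fast = [simulate_genealogy(10, CoalescentModel.exp_growth(5.0), s).tmrca
                for s in range(400)]
        assert np.mean(fast) < np.mean(slow)


class TestExpectedSfs:
    def test_kingman_closed_form_n4(self):
        e = expected_normalized_sfs(4, CoalescentModel.kingman())
        assert e.method == "closed_form"
        assert e.phi == pytest.approx([6 / 11, 3 / 11, 2 / 11])

    def test_phi_sums_to_one(self):
        e = expected_normalized_sfs(30, CoalescentModel.beta(1.3),
                                    reps=2000, seed=0)
        assert abs(e.phi.sum() - 1.0) < 1e-9
        e2 = expected_normalized_sfs(30, CoalescentModel.kingman())
        assert abs(e2.phi.sum() - 1.0) < 1e-12

    def test_beta_alpha2_routes_to_closed_form(self):
        e = expected_normalized_sfs(20, CoalescentModel.beta(2.0))
        assert e.method == "closed_form"
        assert np.array_equal(e.phi, kingman_phi(20))

    def test_growth_zero_rate_equals_kingman_exactly(self):
        for fam in ("exp_growth", "alg_growth"):
            e = expected_normalized_sfs(20, CoalescentModel(fam, 0.0))
            assert np.array_equal(e.phi, kingman_phi(20))

    def test_monte_carlo_kingman_matches_closed_form(self):
        e = expected_normalized_sfs(50, CoalescentModel.kingman(),
                                    reps=20_000, seed=2, method="monte_carlo")
        z = np.abs(e.phi - kingman_phi(50)) / e.se
        assert z.max() < 4.0

    def test_exact_enumeration_oracle_beta(self):
        oracle = exact_phi(6, beta_lambda(1.5))
        e = expected_normalized_sfs(6, CoalescentModel.beta(1.5),
                                    reps=200_000, seed=3)
        assert np.abs(e.phi - oracle).max() < 4 * e.se.max() + 1e-4

    def test_exact_enumeration_oracle_dirac(self):
        oracle = exact_phi(6, dirac_lambda(0.3))
        e = expected_normalized_sfs(6, CoalescentModel.dirac(0.3),
                                    reps=200_000, seed=4)
        assert np.abs(e.phi - oracle).max() < 4 * e.se.max() + 1e-4

    def test_msprime_beta_coalescent_cross_check(self):
        """Normalized branch AFS from msprime agrees for Beta(0.5, 1.5)."""
        import msprime

        n, reps = 20, 3000
        afs = np.zeros(n - 1)
        sq = np.zeros(n - 1)
        sims = msprime.sim_ancestry(
            samples=n, ploidy=1, model=msprime.BetaCoalescent(alpha=1.5),
            num_replicates=reps, random_seed=99)
        for ts in sims:
            a = ts.allele_frequency_spectrum(mode="branch", polarised=True,
                                             span_normalise=False)[1:-1]
            afs += a
            sq += a * a
        phi_ms = afs / afs.sum()
        se_ms = np.sqrt((sq / reps - (afs / reps) ** 2) / reps) / (afs.sum() / reps)
        e = expected_normalized_sfs(n, CoalescentModel.beta(1.5),
                                    reps=100_000, seed=5)
        z = np.abs(e.phi - phi_ms) / np.sqrt(e.se**2 + se_ms**2)
        assert z.max() < 4.0

    def test_singleton_weight_monotone_in_alpha(self):
        phis = [expected_normalized_sfs(50, CoalescentModel.beta(a),
                                        reps=30_000, seed=6).phi[0]
                for a in (1.0, 1.5)]
        assert phis[0] > phis[1] > kingman_phi(50)[0]

    def test_singleton_weight_monotone_in_psi(self):
        phis = [expected_normalized_sfs(50, CoalescentModel.dirac(p),
                                        reps=30_000, seed=7).phi[0]
                for p in (0.05, 0.3, 0.6)]
        assert phis[0] < phis[1] < phis[2]

    def test_cache_returns_identical_object(self):
        a = expected_normalized_sfs(15, CoalescentModel.beta(1.4),
                                    reps=500, seed=8)
        b = expected_normalized_sfs(15, CoalescentModel.beta(1.4),
                                    reps=500, seed=8)
        assert a is b
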