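"""Bipartite network metrics: d', Barber Q, DIRTLPAwb+, Patefield nulls, CPness."""

import itertools

import numpy as np
import pytest

from dominet import (
    VisitationMatrix,
    barber_modularity,
    core_periphery,
    dirt_lpawb_plus,
    modularity_zscore,
    patefield_sample,
    planted_partition_matrix,
    specialization_d,
)
from dominet.network import _block_loglik, _greedy_dmax, _kl

from conftest import random_visitation


def kl_over_compositions(total, q):
    """Exhaustive max of the KL summand over integer allocations (oracle)."""
    best = -np.inf
    k = len(q)

    def rec(i, left, alloc):
        nonlocal best
        if i == k - 1:
            alloc[i] = left
            best = max(best, _kl(np.array(alloc), total, q))
            return
        for a in range(left + 1):
            alloc[i] = a
            rec(i + 1, left - a, alloc)

    rec(0, total, [0] * k)
    return best


class TestSpecialization:
    def test_perfect_reciprocal_specialists(self):
        m = VisitationMatrix(["r1", "r2"], ["c1", "c2"], [[5, 0], [0, 5]])
        assert list(specialization_d(m).d_prime) == [1.0, 1.0]

    def test_usage_proportional_to_availability(self):
        m = VisitationMatrix(["r1", "r2"], ["c1", "c2"], [[1, 1], [1, 1]])
        res = specialization_d(m)
        assert list(res.table["d"]) == pytest.approx([0.0, 0.0])
        assert list(res.d_prime) == [0.0, 0.0]

    def test_dmax_matches_exhaustive_composition_search(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            A = rng.integers(0, 4, size=(3, 4))
            if A.sum() == 0 or A.sum() > 12:
                continue
            colsum = A.sum(axis=0)
            if np.any(colsum == 0):
                continue
            q = colsum / A.sum()
            for i in range(3):
                R = int(A[i].sum())
                if R == 0:
                    continue
                greedy = _kl(_greedy_dmax(R, q), R, q)
                assert greedy == pytest.approx(kl_over_compositions(R, q), abs=1e-10)

    def test_d_prime_in_unit_interval_random_matrices(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            m = random_visitation(rng, int(rng.integers(2, 6)), int(rng.integers(2, 7)))
            if m.F == 0:
                continue
            dp = specialization_d(m).d_prime.dropna()
            assert ((dp >= 0) & (dp <= 1)).all()

    def test_zero_row_flagged_not_raised(self):
        m = VisitationMatrix(["r1", "r2"], ["c1", "c2"], [[3, 1], [0, 0]])
        res = specialization_d(m)
        assert np.isnan(res.d_prime["r2"])
        assert res.table.loc["r2", "degree"] == 0

    def test_cols_guild_is_transpose(self):
        rng = np.random.default_rng(2)
        m = random_visitation(rng, 4, 5)
        a = specialization_d(m, guild="cols").d_prime
        b = specialization_d(m.transpose()).d_prime
        assert a.equals(b)


class TestBarberModularity:
    def test_identity_two_singleton_modules(self):
        m = VisitationMatrix(["r1", "r2"], ["c1", "c2"], np.eye(2))
        assert barber_modularity(m, [0, 1], [0, 1]) == pytest.approx(0.5)

    def test_uniform_matrix_single_module_is_zero(self):
        m = VisitationMatrix(["r1", "r2"], ["c1", "c2"], np.ones((2, 2)))
        assert barber_modularity(m, [0, 0], [0, 0]) == pytest.approx(0.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        m = random_visitation(rng, 5, 4)
        rl = rng.integers(0, 3, 5)
        cl = rng.integers(0, 3, 4)
        q0 = barber_modularity(m, rl, cl)
        perm_r = rng.permutation(5)
        perm_c = rng.permutation(4)
        m2 = VisitationMatrix(
            [m.row_labels[i] for i in perm_r],
            [m.col_labels[j] for j in perm_c],
            m.A[np.ix_(perm_r, perm_c)],
        )
        assert barber_modularity(m2, rl[perm_r], cl[perm_c]) == pytest.approx(q0)

    def test_label_length_mismatch(self):
        m = VisitationMatrix(["r1"], ["c1", "c2"], [[1, 2]])
        with pytest.raises(ValueError):
            barber_modularity(m, [0, 0], [0, 1])


class TestDirtLpawbPlus:
    def test_block_diagonal_recovery_and_self_consistency(self):
        m, rg, cg = planted_partition_matrix(3, 3, 3, 20, 0.0, seed=4)
        part = dirt_lpawb_plus(m, n_runs=10, seed=0)
        assert part.n_modules == 3
        # modules coincide with planted blocks (up to relabelling)
        for g in range(3):
            assert len(set(part.row_modules[rg == g])) == 1
        q_hand = barber_modularity(m, part.row_modules.to_numpy(), part.col_modules.to_numpy())
        assert part.Q == pytest.approx(q_hand, abs=1e-12)

    def test_single_cell_single_module(self):
        m = VisitationMatrix(["r1"], ["c1"], [[7]])
        part = dirt_lpawb_plus(m, n_runs=3, seed=0)
        assert part.n_modules == 1
        assert part.Q == pytest.approx(0.0)

    def test_q_at_least_trivial_partition(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            m = random_visitation(rng, 5, 6)
            if m.F == 0:
                continue
            assert dirt_lpawb_plus(m, n_runs=5, seed=1).Q >= -1e-12

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(1)
        m = random_visitation(rng, 8, 7)
        a = dirt_lpawb_plus(m, n_runs=10, seed=5)
        b = dirt_lpawb_plus(m, n_runs=10, seed=5)
        assert a.Q == b.Q
        assert a.row_modules.equals(b.row_modules)

    def test_invalid_runs(self):
        m = VisitationMatrix(["r1"], ["c1"], [[1]])
        with pytest.raises(ValueError):
            dirt_lpawb_plus(m, n_runs=0)


class TestPatefield:
    def test_margins_conserved_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            r = rng.integers(0, 30, size=rng.integers(2, 6))
            c = rng.multinomial(r.sum(), rng.dirichlet(np.ones(rng.integers(2, 6))))
            T = patefield_sample(r, c, rng)
            np.testing.assert_array_equal(T.sum(axis=1), r)
            np.testing.assert_array_equal(T.sum(axis=0), c)

    def test_two_by_two_enumeration_frequencies(self):
        # margins (1,1)/(1,1): exactly two feasible tables, each probability 1/2
        rng = np.random.default_rng(7)
        hits = sum(patefield_sample([1, 1], [1, 1], rng)[0, 0] for _ in range(10_000))
        assert abs(hits / 10_000 - 0.5) < 0.02

    def test_cell_means_match_hypergeometric_expectation(self):
        rng = np.random.default_rng(12)
        r = np.array([12, 5, 9])
        c = np.array([10, 6, 10])
        n_draws = 20_000
        acc = np.zeros((3, 3))
        for _ in range(n_draws):
            acc += patefield_sample(r, c, rng)
        mean = acc / n_draws
        expected = np.outer(r, c) / r.sum()
        # 3 Monte-Carlo SEs, with sqrt(expected) as a generous sd bound
        tol = 3 * np.sqrt(expected) / np.sqrt(n_draws) + 1e-9
        assert np.all(np.abs(mean - expected) < tol)

    def test_margin_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="does not equal"):
            patefield_sample([2, 2], [1, 1], rng)


class TestModularityZscore:
    def test_planted_structure_strongly_nonrandom(self):
        m, _, _ = planted_partition_matrix(3, 3, 3, 20, 0.2, seed=3)
        part = modularity_zscore(m, n_null=30, n_runs=10, seed=0)
        assert part.z > 3
        assert part.n_null == 30

    def test_null_draw_is_calibrated(self):
        rng = np.random.default_rng(100)
        r = np.array([40, 25, 30, 20, 15])
        c = np.array([35, 30, 25, 20, 20])
        ok = 0
        for seed in range(10):
            A = patefield_sample(r, c, rng)
            m = VisitationMatrix([f"r{i}" for i in range(5)], [f"c{j}" for j in range(5)], A)
            if abs(modularity_zscore(m, n_null=30, n_runs=10, seed=seed).z) <= 3:
                ok += 1
        assert ok >= 9

    def test_zero_nulls_rejected(self):
        m = VisitationMatrix(["r1"], ["c1"], [[1]])
        with pytest.raises(ValueError):
            modularity_zscore(m, n_null=0)


class TestCorePeriphery:
    def test_interactions_concentrated_on_core(self):
        # two busy species per guild carry all the weight -> CPness = 1
        A = np.zeros((4, 4))
        A[:2, :2] = [[10, 8], [7, 9]]
        m = VisitationMatrix([f"r{i}" for i in range(4)], [f"c{j}" for j in range(4)], A)
        cp = core_periphery(m)
        assert cp.cpness == pytest.approx(1.0)
        assert list(cp.row_core) == [True, True, False, False]
        assert cp.E22 == 0

    def test_blocks_sum_to_total(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            m = random_visitation(rng, 4, 5)
            if m.F == 0:
                continue
            cp = core_periphery(m)
            assert cp.E11 + cp.E12 + cp.E21 + cp.E22 == pytest.approx(m.F)
            assert 0 <= cp.cpness <= 1

    def test_greedy_matches_exhaustive_likelihood_search(self):
        rng = np.random.default_rng(77)
        for _ in range(8):
            m = random_visitation(rng, 4, 4, scale=6)
            if m.F == 0:
                continue
            rdeg, cdeg, F = m.A.sum(1), m.A.sum(0), m.F
            best_ll = -np.inf
            for rbits in itertools.product([True, False], repeat=4):
                for cbits in itertools.product([True, False], repeat=4):
                    ll = _block_loglik(m.A, np.array(rbits), np.array(cbits), rdeg, cdeg, F)
                    best_ll = max(best_ll, ll)
            cp = core_periphery(m)
            ll_found = _block_loglik(
                m.A, cp.row_core.to_numpy(), cp.col_core.to_numpy(), rdeg, cdeg, F
            )
            assert ll_found == pytest.approx(best_ll, abs=1e-8)

    def test_single_species_guild_all_core(self):
        m = VisitationMatrix(["r1"], ["c1", "c2"], [[4, 1]])
        cp = core_periphery(m)
        assert bool(cp.row_core.iloc[0])
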