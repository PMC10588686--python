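"""Dominance ranking: David's score, dyadic probabilities, ranks, certainty."""

import numpy as np
import pandas as pd
import pytest

from dominet import (
    AgonisticMatrix,
    davids_score,
    dominance_probabilities,
    filter_uncertain_species,
    rank_and_certainty,
    rank_species,
    tournament_summary,
)
from dominet.dominance import exhaustive_rank

from conftest import random_tournament


def brute_force_davids(W: np.ndarray) -> np.ndarray:
    """Materialize every P term with explicit loops (independent oracle)."""
    n = W.shape[0]
    P = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j and W[i, j] + W[j, i] > 0:
                P[i, j] = W[i, j] / (W[i, j] + W[j, i])
    w = np.zeros(n)
    l = np.zeros(n)
    for i in range(n):
        for j in range(n):
            w[i] += P[i, j]
            l[i] += P[j, i]
    ds = np.zeros(n)
    for i in range(n):
        w2 = sum(P[i, j] * w[j] for j in range(n))
        l2 = sum(P[j, i] * l[j] for j in range(n))
        ds[i] = w[i] + w2 - l[i] - l2
    return ds


class TestDavidsScore:
    def test_single_dyad_closed_form(self):
        W = AgonisticMatrix(["A", "B"], [[0, 4], [0, 0]])
        ds = davids_score(W)
        assert ds["A"] == pytest.approx(1.0)
        assert ds["B"] == pytest.approx(-1.0)

    def test_transitive_chain_hand_evaluated(self, chain_tournament):
        ds = davids_score(chain_tournament)
        assert list(ds) == pytest.approx([3.0, 0.0, -3.0])

    def test_matches_bruteforce_oracle_and_sums_to_zero(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(2, 9))
            W = random_tournament(rng, n)
            ds = davids_score(W).to_numpy()
            np.testing.assert_allclose(ds, brute_force_davids(W.W), atol=1e-10)
            assert abs(ds.sum()) < 1e-9

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="no contests"):
            davids_score(AgonisticMatrix(["A", "B"], np.zeros((2, 2))))


class TestDominanceProbabilities:
    def test_direct_dyad_smoothing(self):
        W = AgonisticMatrix(["A", "B"], [[0, 4], [0, 0]])
        P = dominance_probabilities(W, max_path_len=1)
        assert P.loc["A", "B"] == pytest.approx(4.5 / 5)

    def test_uninformative_dyad_is_half(self):
        # C never meets anyone and has no indirect pathways
        W = AgonisticMatrix(list("ABC"), [[0, 4, 0], [1, 0, 0], [0, 0, 0]])
        P = dominance_probabilities(W)
        assert P.loc["A", "C"] == 0.5
        assert P.loc["B", "C"] == 0.5

    def test_complementarity_for_random_matrices(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            W = random_tournament(rng, int(rng.integers(2, 10)))
            P = dominance_probabilities(W).to_numpy()
            np.testing.assert_allclose(P + P.T, 1.0, atol=1e-12)

    def test_indirect_pathway_breaks_tie(self):
        # A>B, B>C observed; A vs C never meet but the A->B->C path informs it
        W = AgonisticMatrix(list("ABC"), [[0, 3, 0], [0, 0, 3], [0, 0, 0]])
        P = dominance_probabilities(W, max_path_len=2, decay=0.5)
        assert P.loc["A", "C"] > 0.5

    @pytest.mark.parametrize("kwargs", [{"max_path_len": 0}, {"decay": 0.0}, {"decay": 1.5}])
    def test_invalid_parameters_rejected(self, kwargs, chain_tournament):
        with pytest.raises(ValueError):
            dominance_probabilities(chain_tournament, **kwargs)


class TestRankAndCertainty:
    def test_matches_exhaustive_permutation_search(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = int(rng.integers(3, 7))
            M = rng.uniform(size=(n, n))
            P = (M + (1 - M.T)) / 2
            np.fill_diagonal(P, 0.5)
            Pdf = pd.DataFrame(P, index=[f"s{k}" for k in range(n)], columns=[f"s{k}" for k in range(n)])
            order, _, _, _ = rank_and_certainty(Pdf, seed=0)
            best = exhaustive_rank(Pdf)
            idx = {s: k for k, s in enumerate(Pdf.index)}
            score = lambda o: np.triu(P[np.ix_([idx[s] for s in o], [idx[s] for s in o])], 1).sum()
            assert score(order) == pytest.approx(score(best), abs=1e-9)

    def test_transitive_matrix_recovers_order_and_certainty(self):
        n = 5
        labels = [f"s{k}" for k in range(n)]
        P = np.where(np.arange(n)[:, None] < np.arange(n)[None, :], 0.9, 0.1)
        np.fill_diagonal(P, 0.5)
        order, rank_index, dc, _ = rank_and_certainty(pd.DataFrame(P, index=labels, columns=labels), seed=1)
        assert order == labels
        np.testing.assert_allclose(dc.to_numpy(), 0.9)
        assert rank_index[labels[0]] == 0.0 and rank_index[labels[-1]] == 1.0

    def test_fully_ambiguous_keeps_input_order(self):
        labels = list("WXYZ")
        P = pd.DataFrame(np.full((4, 4), 0.5), index=labels, columns=labels)
        order, _, dc, dc_sd = rank_and_certainty(P, seed=0)
        assert order == labels
        np.testing.assert_allclose(dc.to_numpy(), 0.5)
        np.testing.assert_allclose(dc_sd.to_numpy(), 0.0)

    def test_two_species_rank_index_endpoints(self):
        P = pd.DataFrame([[0.5, 1.0], [0.0, 0.5]], index=["A", "B"], columns=["A", "B"])
        _, rank_index, _, _ = rank_and_certainty(P, seed=0)
        assert rank_index["A"] == 0.0 and rank_index["B"] == 1.0

    def test_single_species_rejected(self):
        P = pd.DataFrame([[0.5]], index=["A"], columns=["A"])
        with pytest.raises(ValueError):
            rank_and_certainty(P)


class TestFilterUncertain:
    def test_contest_free_species_dropped(self):
        # D never contests: DC exactly 0.5, removed by the default threshold
        W = np.zeros((4, 4))
        W[0, 1] = 4
        W[1, 2] = 4
        W[0, 2] = 4
        M = AgonisticMatrix(list("ABCD"), W)
        res = rank_species(M)
        reduced = filter_uncertain_species(M, res, threshold=0.5)
        assert reduced.labels == list("ABC")

    def test_all_certain_is_identity(self, chain_tournament):
        res = rank_species(chain_tournament)
        reduced = filter_uncertain_species(chain_tournament, res)
        assert reduced.labels == chain_tournament.labels
        np.testing.assert_array_equal(reduced.W, chain_tournament.W)

    def test_all_uncertain_raises(self):
        W = AgonisticMatrix(["A", "B", "C"], np.zeros((3, 3)))
        P = dominance_probabilities(W)
        order, ri, dc, dcsd = rank_and_certainty(P, seed=0)
        from dominet.dominance import DominanceResult

        fake = DominanceResult(Ds=pd.Series(0.0, index=W.labels), P=P,
                               rank_order=order, rank_index=ri, DC_mean=dc, DC_sd=dcsd)
        with pytest.raises(ValueError, match="fewer than 2"):
            filter_uncertain_species(W, fake)


class TestTournamentSummary:
    def test_field_community_rates(self):
        # 477 contests among 13 species spread over 35 observed dyads
        rng = np.random.default_rng(0)
        n = 13
        W = np.zeros((n, n))
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        chosen = [pairs[k] for k in rng.choice(len(pairs), size=35, replace=False)]
        counts = rng.multinomial(477 - 35, np.full(35, 1 / 35)) + 1
        for (i, j), m in zip(chosen, counts):
            W[i, j] = m
        s = tournament_summary(AgonisticMatrix([f"s{k}" for k in range(n)], W))
        assert round(s.per_individual, 1) == 36.7
        assert round(s.per_dyad, 1) == 6.1
        assert s.prop_unknown == pytest.approx(43 / 78)
        assert round(s.prop_unknown, 3) == 0.551

    def test_empty_tournament(self):
        s = tournament_summary(AgonisticMatrix(list("ABCD"), np.zeros((4, 4))))
        assert s.total_interactions == 0
        assert s.per_individual == 0 and s.per_dyad == 0
        assert s.prop_unknown == 1.0
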