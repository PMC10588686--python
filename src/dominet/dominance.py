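"""Species-level dominance hierarchies from agonistic win/loss records.

A community's agonistic data form a square tournament matrix ``W`` where
``W[i, j]`` counts contests that species *i* won against species *j*.
Interspecific tournaments in the field are almost always incomplete: many
dyads are never observed contesting.  The tools here are designed for such
sparse matrices.

Two complementary rankings are provided:

* **David's score** (``davids_score``) — a cardinal index built from dyadic
  win proportions, correcting each species' record by the records of its
  opponents.  Scores sum to zero over the community.
* **Network-based ranking** (``dominance_probabilities`` +
  ``rank_and_certainty``) — dyadic dominance probabilities that pool direct
  contests with indirect win-pathways through common third parties, an
  ordinal rank order maximizing the probability mass above the diagonal,
  and a per-species dominance certainty (DC) between 0.5 (position entirely
  uncertain) and 1 (certain).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AgonisticMatrix",
    "DominanceResult",
    "TournamentSummary",
    "davids_score",
    "dominance_probabilities",
    "rank_and_certainty",
    "rank_species",
    "filter_uncertain_species",
    "tournament_summary",
]


@dataclass
class AgonisticMatrix:
    """Square contest-outcome matrix: ``W[i, j]`` = wins of *i* over *j*."""

    labels: list[str]
    W: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.labels = [str(x) for x in self.labels]
        n = len(self.labels)
        if self.W.shape != (n, n):
            raise ValueError(f"W has shape {self.W.shape}, expected ({n}, {n})")
        if len(set(self.labels)) != n:
            dupes = sorted({x for x in self.labels if self.labels.count(x) > 1})
            raise ValueError(f"duplicate species labels: {dupes}")
        if np.any(self.W < 0):
            raise ValueError("contest counts must be nonnegative")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("diagonal of W must be zero (no self-contests)")

    @property
    def n(self) -> int:
        return len(self.labels)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AgonisticMatrix":
        if list(df.index) != list(df.columns):
            raise ValueError("row and column labels of a tournament must coincide")
        return cls(list(df.index), df.to_numpy(dtype=float))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.W, index=self.labels, columns=self.labels)

    def subset(self, keep: Sequence[str]) -> "AgonisticMatrix":
        idx = [self.labels.index(k) for k in keep]
        return AgonisticMatrix([self.labels[i] for i in idx], self.W[np.ix_(idx, idx)])


@dataclass
class TournamentSummary:
    total_interactions: int
    n_species: int
    per_individual: float
    per_dyad: float
    prop_unknown: float


@dataclass
class DominanceResult:
    """Ranking outputs: David's score, dyadic probabilities, ranks, certainty."""

    Ds: pd.Series
    P: pd.DataFrame
    rank_order: list[str]
    rank_index: pd.Series
    DC_mean: pd.Series
    DC_sd: pd.Series
    annealing_score: float = field(default=float("nan"))


def davids_score(matrix: AgonisticMatrix) -> pd.Series:
    """David's score ``Ds = w + w2 - l - l2`` from dyadic win proportions.

    For each observed dyad the win proportion is
    ``P_ij = W[i, j] / (W[i, j] + W[j, i])``; dyads with no contests
    contribute nothing (the index was designed for incomplete tournaments).
    ``w`` is the sum of a species' win proportions, ``w2`` the win
    proportions of its victims weighted by their own ``w``, and ``l``,
    ``l2`` the mirror-image loss terms.  Scores sum to zero.
    """
    W = matrix.W
    tot = W + W.T
    if not np.any(tot > 0):
        raise ValueError("no contests: all-zero agonistic matrix")
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(tot > 0, W / np.where(tot > 0, tot, 1.0), 0.0)
    np.fill_diagonal(P, 0.0)
    w = P.sum(axis=1)
    l = P.sum(axis=0)
    w2 = P @ w
    l2 = P.T @ l
    ds = w + w2 - l - l2
    return pd.Series(ds, index=matrix.labels, name="Ds")


def dominance_probabilities(
    matrix: AgonisticMatrix,
    max_path_len: int = 2,
    decay: float = 0.5,
) -> pd.DataFrame:
    """Dyadic dominance probabilities pooling direct and indirect pathways.

    Direct contest counts are augmented with counts of directed win-pathways
    through intermediaries: ``N_k[i, j]`` counts length-``k`` chains
    i → … → j in the binarized win-majority graph, down-weighted by
    ``decay**(k-1)``.  The pooled flow ``F`` is converted to a probability
    with add-half smoothing, ``P_ij = (F_ij + 0.5) / (F_ij + F_ji + 1)``,
    so dyads with no information land at exactly 0.5 and the matrix always
    satisfies ``P + P.T == 1``.

    This is an explicit, configurable reconstruction of indirect-pathway
    ranking in the percolation/conductance family; path length and decay
    are knobs, not claims of equivalence to any particular implementation.
    """
    if max_path_len < 1:
        raise ValueError("max_path_len must be >= 1")
    if not (0 < decay <= 1):
        raise ValueError("decay must be in (0, 1]")
    W = matrix.W
    B = (W > W.T).astype(float)  # win-majority digraph
    F = W.astype(float).copy()
    Bk = B.copy()
    for k in range(2, max_path_len + 1):
        Bk = Bk @ B
        F += decay ** (k - 1) * Bk
    np.fill_diagonal(F, 0.0)
    P = (F + 0.5) / (F + F.T + 1.0)
    np.fill_diagonal(P, 0.5)
    return pd.DataFrame(P, index=matrix.labels, columns=matrix.labels)


def _order_score(P: np.ndarray, order: np.ndarray) -> float:
    sub = P[np.ix_(order, order)]
    return float(np.triu(sub, k=1).sum())


def _anneal_once(
    P: np.ndarray,
    rng: np.random.Generator,
    start: np.ndarray,
    n_steps: int,
    t0: float,
    cooling: float,
) -> tuple[np.ndarray, float]:
    n = len(start)
    order = start.copy()
    score = _order_score(P, order)
    best, best_score = order.copy(), score
    t = t0
    for _ in range(n_steps):
        i, j = rng.integers(0, n, size=2)
        if i == j:
            t *= cooling
            continue
        cand = order.copy()
        cand[i], cand[j] = cand[j], cand[i]
        s = _order_score(P, cand)
        if s > score or rng.random() < np.exp((s - score) / max(t, 1e-12)):
            order, score = cand, s
            if score > best_score:
                best, best_score = order.copy(), score
        t *= cooling
    return best, best_score


def _hill_climb(P: np.ndarray, order: np.ndarray) -> tuple[np.ndarray, float]:
    # strict-improvement pairwise swaps; keeps ties at the incoming order
    n = len(order)
    order = order.copy()
    score = _order_score(P, order)
    improved = True
    while improved:
        improved = False
        for i in range(n - 1):
            for j in range(i + 1, n):
                cand = order.copy()
                cand[i], cand[j] = cand[j], cand[i]
                s = _order_score(P, cand)
                if s > score + 1e-12:
                    order, score = cand, s
                    improved = True
    return order, score


def rank_and_certainty(
    P: pd.DataFrame,
    n_restarts: int = 10,
    n_steps: int = 400,
    seed: int | None = 0,
) -> tuple[list[str], pd.Series, pd.Series, pd.Series]:
    """Ordinal ranks and dominance certainty from a probability matrix.

    The rank order maximizes the sum of above-diagonal dominance
    probabilities, searched by seeded simulated annealing (geometric
    cooling) with restarts plus a strict-improvement hill-climb; exact for
    small communities (checked against exhaustive permutation search).
    Ties are broken in favour of the input species order.  The rank index
    maps the top-ranked species to 0 and the bottom-ranked to 1.

    DC for species *i* is the mean over opponents *j* of
    ``max(P_ij, P_ji)``: 0.5 means its position is entirely uncertain,
    1 means every pairwise relationship is settled.
    """
    n = P.shape[0]
    if n < 2:
        raise ValueError("need at least 2 species to rank")
    labels = list(P.index)
    M = P.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    # identity start first so a fully ambiguous matrix keeps the input order
    best, best_score = _hill_climb(M, np.arange(n))
    for _ in range(n_restarts):
        start = rng.permutation(n)
        order, _ = _anneal_once(M, rng, start, n_steps=n_steps, t0=1.0, cooling=0.99)
        order, score = _hill_climb(M, order)
        if score > best_score + 1e-12:
            best, best_score = order, score

    rank_order = [labels[i] for i in best]
    pos = np.empty(n)
    pos[best] = np.arange(n)
    rank_index = pd.Series(pos / (n - 1), index=labels, name="rank_index")

    off = ~np.eye(n, dtype=bool)
    certain = np.maximum(M, M.T)
    dc_mean = np.array([certain[i, off[i]].mean() for i in range(n)])
    dc_sd = np.array(
        [certain[i, off[i]].std(ddof=1) if n > 2 else 0.0 for i in range(n)]
    )
    return (
        rank_order,
        rank_index,
        pd.Series(dc_mean, index=labels, name="DC_mean"),
        pd.Series(dc_sd, index=labels, name="DC_sd"),
    )


def exhaustive_rank(P: pd.DataFrame) -> list[str]:
    """Brute-force optimal rank order (n <= 9); reference for the annealer."""
    labels = list(P.index)
    M = P.to_numpy(dtype=float)
    n = len(labels)
    if n > 9:
        raise ValueError("exhaustive search is limited to n <= 9")
    best, best_score = None, -np.inf
    for perm in itertools.permutations(range(n)):
        s = _order_score(M, np.array(perm))
        if s > best_score + 1e-12:
            best, best_score = perm, s
    return [labels[i] for i in best]


def rank_species(
    matrix: AgonisticMatrix,
    max_path_len: int = 2,
    decay: float = 0.5,
    seed: int | None = 0,
) -> DominanceResult:
    """Full dominance workup: David's score, probabilities, ranks, DC."""
    ds = davids_score(matrix)
    P = dominance_probabilities(matrix, max_path_len=max_path_len, decay=decay)
    order, rank_index, dc_mean, dc_sd = rank_and_certainty(P, seed=seed)
    score = _order_score(P.to_numpy(), np.array([list(P.index).index(s) for s in order]))
    return DominanceResult(
        Ds=ds,
        P=P,
        rank_order=order,
        rank_index=rank_index,
        DC_mean=dc_mean,
        DC_sd=dc_sd,
        annealing_score=score,
    )


def filter_uncertain_species(
    matrix: AgonisticMatrix,
    result: DominanceResult,
    threshold: float = 0.5,
) -> AgonisticMatrix:
    """Drop species whose dominance certainty does not exceed ``threshold``.

    Species observed in too few contests can sit at DC = 0.5 (no information
    about their position); the community matrix is regenerated without them
    and downstream ranking should be recomputed on the reduced matrix.
    """
    if not (0.5 <= threshold <= 1):
        raise ValueError("threshold must lie in [0.5, 1]")
    keep = [s for s in matrix.labels if result.DC_mean[s] > threshold]
    if len(keep) < 2:
        raise ValueError(
            f"fewer than 2 species exceed DC threshold {threshold}; cannot rank"
        )
    return matrix.subset(keep)


def tournament_summary(matrix: AgonisticMatrix) -> TournamentSummary:
    """Sampling-intensity summary of an agonistic tournament.

    ``per_individual`` = contests per species, ``per_dyad`` = contests per
    unordered species pair, ``prop_unknown`` = share of dyads never observed
    contesting.  Values are exact; round only when reporting.
    """
    n = matrix.n
    if n < 2:
        raise ValueError("need at least 2 species")
    total = int(round(matrix.W.sum()))
    n_dyads = n * (n - 1) // 2
    sym = matrix.W + matrix.W.T
    iu = np.triu_indices(n, k=1)
    unknown = int(np.sum(sym[iu] == 0))
    return TournamentSummary(
        total_interactions=total,
        n_species=n,
        per_individual=total / n,
        per_dyad=total / n_dyads,
        prop_unknown=unknown / n_dyads,
    )
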