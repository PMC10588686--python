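"""Quantitative bipartite network structure: specialization, modularity, core-periphery.

The community is a weighted bipartite network: one guild in the rows
(consumers, e.g. hummingbird species), one in the columns (resources, e.g.
plant species), cell ``a_ij`` the number of visits.  Interaction *frequency*
carries the signal here, so every statistic is weighted:

* ``specialization_d`` — the Kullback-Leibler specialization index d' per
  species, the deviation of its partner-use distribution from partner
  availability, rescaled between its achievable minimum and maximum
  (0 = perfect generalist, 1 = perfect specialist).
* ``dirt_lpawb_plus`` — weighted bipartite (Barber) modularity Q maximized
  by restart-wrapped label propagation plus hill-climbing.
* ``patefield_sample`` / ``modularity_zscore`` — fixed-margins null model
  and the z-score of observed Q against the null ensemble.
* ``core_periphery`` — 2x2 block core/periphery partition and the CPness
  statistic, the fraction of interaction weight outside the
  periphery-periphery block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VisitationMatrix",
    "SpecializationResult",
    "ModulePartition",
    "CorePeriphery",
    "specialization_d",
    "barber_modularity",
    "dirt_lpawb_plus",
    "patefield_sample",
    "modularity_zscore",
    "core_periphery",
]


@dataclass
class VisitationMatrix:
    """Weighted bipartite interaction matrix (rows x columns, visit counts)."""

    row_labels: list[str]
    col_labels: list[str]
    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.row_labels = [str(x) for x in self.row_labels]
        self.col_labels = [str(x) for x in self.col_labels]
        if self.A.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError(
                f"matrix shape {self.A.shape} does not match labels "
                f"({len(self.row_labels)}, {len(self.col_labels)})"
            )
        for labs, axis in ((self.row_labels, "row"), (self.col_labels, "column")):
            if len(set(labs)) != len(labs):
                dupes = sorted({x for x in labs if labs.count(x) > 1})
                raise ValueError(f"duplicate {axis} labels: {dupes}")
        if np.any(self.A < 0):
            raise ValueError("interaction weights must be nonnegative")

    @property
    def F(self) -> float:
        """Grand total interaction weight."""
        return float(self.A.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.A.shape

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "VisitationMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.A, index=self.row_labels, columns=self.col_labels)

    def transpose(self) -> "VisitationMatrix":
        return VisitationMatrix(self.col_labels, self.row_labels, self.A.T)


@dataclass
class SpecializationResult:
    table: pd.DataFrame  # columns: degree, d, d_min, d_max, d_prime

    @property
    def d_prime(self) -> pd.Series:
        return self.table["d_prime"]


@dataclass
class ModulePartition:
    row_modules: pd.Series
    col_modules: pd.Series
    Q: float
    n_modules: int
    n_runs: int
    null_mean: float = field(default=float("nan"))
    null_sd: float = field(default=float("nan"))
    z: float = field(default=float("nan"))
    n_null: int = 0


@dataclass
class CorePeriphery:
    row_core: pd.Series
    col_core: pd.Series
    E11: float
    E12: float
    E21: float
    E22: float
    cpness: float


# ---------------------------------------------------------------------------
# specialization d'
# ---------------------------------------------------------------------------


def _largest_remainder(total: int, q: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` units as proportional to ``q`` as possible."""
    ideal = total * q / q.sum()
    alloc = np.floor(ideal).astype(int)
    rem = total - alloc.sum()
    if rem > 0:
        frac = ideal - alloc
        # ties broken by lower index (stable argsort on negated fractions)
        order = np.argsort(-frac, kind="stable")
        alloc[order[:rem]] += 1
    return alloc


def _kl(alloc: np.ndarray, total: int, q: np.ndarray) -> float:
    p = alloc / total
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def _greedy_dmax(total: int, q: np.ndarray) -> np.ndarray:
    """Load ``total`` integer units to maximize the KL summand, one at a time."""
    alloc = np.zeros(len(q), dtype=int)
    order = np.argsort(q, kind="stable")  # prefer rarest partners on ties
    for _ in range(total):
        best_j, best_val = -1, -np.inf
        for j in order:
            alloc[j] += 1
            val = _kl(alloc, total, q)
            alloc[j] -= 1
            if val > best_val + 1e-15:
                best_j, best_val = j, val
        alloc[best_j] += 1
    return alloc


def specialization_d(matrix: VisitationMatrix, guild: str = "rows") -> SpecializationResult:
    """Kullback-Leibler specialization index d' per species of one guild.

    For species *i* with partner-use proportions ``p_ij = a_ij / rowsum_i``
    and partner availability ``q_j = colsum_j / F``,
    ``d_i = sum_j p_ij * ln(p_ij / q_j)``.  ``d_min`` is the KL value of the
    most proportional-to-availability *integer* reallocation of the row
    total (largest-remainder rule) and ``d_max`` that of the greedy
    unit-by-unit loading onto the rarest partners;
    ``d' = (d - d_min) / (d_max - d_min)`` clamped to [0, 1].

    Rows with zero total get ``d' = NaN`` (undefined, excluded from
    downstream regressions) rather than an exception.
    """
    if guild not in ("rows", "cols"):
        raise ValueError("guild must be 'rows' or 'cols'")
    if guild == "cols":
        matrix = matrix.transpose()
    A = matrix.A
    F = matrix.F
    if F <= 0:
        raise ValueError("empty network: no interactions")
    colsum = A.sum(axis=0)
    avail = colsum > 0
    q = colsum[avail] / F
    rows = []
    for i, lab in enumerate(matrix.row_labels):
        R = A[i].sum()
        degree = int(np.count_nonzero(A[i]))
        if R <= 0:
            rows.append((lab, 0, np.nan, np.nan, np.nan, np.nan))
            continue
        Ri = int(round(R))
        p = A[i, avail] / R
        mask = p > 0
        d = float(np.sum(p[mask] * np.log(p[mask] / q[mask])))
        d_min = _kl(_largest_remainder(Ri, q), Ri, q)
        d_max = _kl(_greedy_dmax(Ri, q), Ri, q)
        if d_max - d_min < 1e-12:
            d_prime = 0.0
        else:
            d_prime = float(np.clip((d - d_min) / (d_max - d_min), 0.0, 1.0))
        rows.append((lab, degree, d, d_min, d_max, d_prime))
    table = pd.DataFrame(
        rows, columns=["species", "degree", "d", "d_min", "d_max", "d_prime"]
    ).set_index("species")
    return SpecializationResult(table=table)


# ---------------------------------------------------------------------------
# Barber modularity and its maximization
# ---------------------------------------------------------------------------


def barber_modularity(
    matrix: VisitationMatrix,
    row_modules: Sequence[int],
    col_modules: Sequence[int],
) -> float:
    """Weighted bipartite modularity Q of a given module assignment.

    ``Q = (1/F) * sum_ij (a_ij - rowsum_i * colsum_j / F) * [g_i == h_j]``
    where ``g``/``h`` are the row/column module labels.
    """
    rl = np.asarray(row_modules)
    cl = np.asarray(col_modules)
    A = matrix.A
    if rl.shape[0] != A.shape[0] or cl.shape[0] != A.shape[1]:
        raise ValueError("module label lengths do not match matrix dimensions")
    F = matrix.F
    if F <= 0:
        raise ValueError("empty network")
    same = rl[:, None] == cl[None, :]
    expected = np.outer(A.sum(axis=1), A.sum(axis=0)) / F
    return float(((A - expected) * same).sum() / F)


def _q_from_labels(A, rdeg, cdeg, F, rl, cl, n_mod):
    e = np.zeros(n_mod)
    a = np.zeros(n_mod)
    b = np.zeros(n_mod)
    for m in range(n_mod):
        rm = rl == m
        cm = cl == m
        if rm.any() and cm.any():
            e[m] = A[np.ix_(rm, cm)].sum()
        a[m] = rdeg[rm].sum()
        b[m] = cdeg[cm].sum()
    return (e.sum() - (a * b).sum() / F) / F


def _propagate(A, rdeg, cdeg, F, rl, cl):
    """Alternate best-label assignment between guilds until Q stops improving."""
    n_r, n_c = A.shape
    q = _q_from_labels(A, rdeg, cdeg, F, rl, cl, max(rl.max(), cl.max()) + 1)
    while True:
        labels = np.unique(np.concatenate([rl, cl]))
        # rows: w_im (weight to columns of module m) vs degree-expected share
        Wc = np.zeros((n_r, len(labels)))
        Bm = np.zeros(len(labels))
        for k, m in enumerate(labels):
            cm = cl == m
            Wc[:, k] = A[:, cm].sum(axis=1)
            Bm[k] = cdeg[cm].sum()
        gain = Wc - np.outer(rdeg, Bm) / F
        rl = labels[np.argmax(gain, axis=1)]
        # columns
        Wr = np.zeros((n_c, len(labels)))
        Am = np.zeros(len(labels))
        for k, m in enumerate(labels):
            rm = rl == m
            Wr[:, k] = A[rm, :].sum(axis=0)
            Am[k] = rdeg[rm].sum()
        gain = Wr - np.outer(cdeg, Am) / F
        cl = labels[np.argmax(gain, axis=1)]
        q_new = _q_from_labels(A, rdeg, cdeg, F, rl, cl, max(rl.max(), cl.max()) + 1)
        if q_new <= q + 1e-12:
            return rl, cl, q_new
        q = q_new


def _merge_step(A, rdeg, cdeg, F, rl, cl):
    """Best module merge if it improves Q; returns (rl, cl, improved)."""
    labels = np.unique(np.concatenate([rl, cl]))
    if len(labels) < 2:
        return rl, cl, False
    k = len(labels)
    E = np.zeros((k, k))
    a = np.zeros(k)
    b = np.zeros(k)
    for i, m in enumerate(labels):
        rm = rl == m
        a[i] = rdeg[rm].sum()
        b[i] = cdeg[cl == m].sum()
        for j, m2 in enumerate(labels):
            E[i, j] = A[np.ix_(rm, cl == m2)].sum()
    best = (0.0, None)
    for i in range(k):
        for j in range(i + 1, k):
            dq = (E[i, j] + E[j, i] - (a[i] * b[j] + a[j] * b[i]) / F) / F
            if dq > best[0] + 1e-12:
                best = (dq, (labels[i], labels[j]))
    if best[1] is None:
        return rl, cl, False
    m1, m2 = best[1]
    rl = np.where(rl == m2, m1, rl)
    cl = np.where(cl == m2, m1, cl)
    return rl, cl, True


def _relabel_first_appearance(rl, cl):
    mapping: dict[int, int] = {}
    for lab in list(rl) + list(cl):
        if lab not in mapping:
            mapping[lab] = len(mapping)
    return (
        np.array([mapping[x] for x in rl], dtype=int),
        np.array([mapping[x] for x in cl], dtype=int),
    )


def dirt_lpawb_plus(
    matrix: VisitationMatrix,
    n_runs: int = 50,
    seed: int | None = 0,
) -> ModulePartition:
    """Maximize weighted bipartite modularity by restarted label propagation.

    Each run initializes the column labels with a run-dependent number of
    random modules, alternates best-label propagation between the two
    guilds, and then interleaves strict-improvement module merges with
    further propagation until Q stops increasing.  The best partition over
    ``n_runs`` runs is returned, modules relabelled 0..k-1 in order of
    first appearance.  Deterministic given ``seed``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    A = matrix.A
    if matrix.F <= 0:
        raise ValueError("empty network")
    n_r, n_c = A.shape
    rdeg = A.sum(axis=1)
    cdeg = A.sum(axis=0)
    F = matrix.F
    rng = np.random.default_rng(seed)
    max_k = max(n_c, 1)
    best_q, best_rl, best_cl = -np.inf, None, None
    for run in range(n_runs):
        if run == 0:
            cl = np.arange(n_c)  # every column its own module
        else:
            k = 1 + rng.integers(0, max_k)
            cl = rng.integers(0, k, size=n_c)
        rl = np.full(n_r, cl[0] if n_c else 0)
        rl, cl, q = _propagate(A, rdeg, cdeg, F, rl, cl)
        improved = True
        while improved:
            rl, cl, improved = _merge_step(A, rdeg, cdeg, F, rl, cl)
            if improved:
                rl, cl, q = _propagate(A, rdeg, cdeg, F, rl, cl)
        if q > best_q + 1e-12:
            best_q, best_rl, best_cl = q, rl, cl
    rl, cl = _relabel_first_appearance(best_rl, best_cl)
    q_final = barber_modularity(matrix, rl, cl)
    return ModulePartition(
        row_modules=pd.Series(rl, index=matrix.row_labels, name="module"),
        col_modules=pd.Series(cl, index=matrix.col_labels, name="module"),
        Q=q_final,
        n_modules=int(len(np.unique(np.concatenate([rl, cl])))),
        n_runs=n_runs,
    )


# ---------------------------------------------------------------------------
# fixed-margins null model
# ---------------------------------------------------------------------------


def patefield_sample(
    row_margins: Sequence[int],
    col_margins: Sequence[int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform random count table with the given row and column totals.

    Sequential conditional filling: row *i* is a multivariate-hypergeometric
    draw of its total against the not-yet-allocated column totals, which
    yields the uniform distribution over all tables with the fixed margins.
    """
    r = np.asarray(row_margins, dtype=int)
    c = np.asarray(col_margins, dtype=int)
    if np.any(r < 0) or np.any(c < 0):
        raise ValueError("margins must be nonnegative")
    if r.sum() != c.sum():
        raise ValueError(
            f"row total {r.sum()} does not equal column total {c.sum()}"
        )
    out = np.zeros((len(r), len(c)), dtype=int)
    remaining = c.copy()
    for i, ri in enumerate(r):
        draw = rng.multivariate_hypergeometric(remaining, int(ri))
        out[i] = draw
        remaining -= draw
    return out


def modularity_zscore(
    matrix: VisitationMatrix,
    n_null: int = 100,
    n_runs: int = 50,
    seed: int | None = 0,
) -> ModulePartition:
    """Observed modularity against a fixed-margins (Patefield) null ensemble.

    The observed network and every null replicate get the same search
    budget (``n_runs`` restarts of the label-propagation maximizer), so the
    z-score is not inflated by asymmetric optimization.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    part = dirt_lpawb_plus(matrix, n_runs=n_runs, seed=seed)
    rng = np.random.default_rng(seed)
    r = np.rint(matrix.A.sum(axis=1)).astype(int)
    c = np.rint(matrix.A.sum(axis=0)).astype(int)
    q_null = np.empty(n_null)
    for b in range(n_null):
        null_A = patefield_sample(r, c, rng)
        null_m = VisitationMatrix(matrix.row_labels, matrix.col_labels, null_A)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        q_null[b] = dirt_lpawb_plus(null_m, n_runs=n_runs, seed=sub_seed).Q
    mean, sd = float(q_null.mean()), float(q_null.std(ddof=1))
    if sd == 0:
        warnings.warn("null ensemble has zero spread; z reported as +inf")
        z = float("inf") if part.Q > mean else float("-inf")
    else:
        z = (part.Q - mean) / sd
    part.null_mean, part.null_sd, part.z, part.n_null = mean, sd, z, n_null
    return part


# ---------------------------------------------------------------------------
# core-periphery
# ---------------------------------------------------------------------------


def _block_loglik(A, rcore, ccore, rdeg, cdeg, F):
    """Poisson 2x2-block log-likelihood of a core assignment.

    Each block has its own rate; ``ll = sum_b e_b * ln(e_b / n_b) - e_b``
    (cells ``n_b``, weight ``e_b``, 0 ln 0 = 0).  Deliberately NOT
    degree-corrected: core-periphery is a degree phenomenon, and a
    degree-corrected objective absorbs exactly the structure being sought.
    """
    ll = 0.0
    for rmask in (rcore, ~rcore):
        for cmask in (ccore, ~ccore):
            e = A[np.ix_(rmask, cmask)].sum()
            if e > 0:
                n_cells = rmask.sum() * cmask.sum()
                ll += e * np.log(e / n_cells) - e
    return ll


def _greedy_cp(A, rdeg, cdeg, F, rcore0, ccore0):
    rcore, ccore = rcore0.copy(), ccore0.copy()
    ll = _block_loglik(A, rcore, ccore, rdeg, cdeg, F)
    improved = True
    while improved:
        improved = False
        best = (ll, None)
        for side, n in (("r", len(rcore)), ("c", len(ccore))):
            for i in range(n):
                if side == "r":
                    rcore[i] = ~rcore[i]
                    cand = _block_loglik(A, rcore, ccore, rdeg, cdeg, F)
                    rcore[i] = ~rcore[i]
                else:
                    ccore[i] = ~ccore[i]
                    cand = _block_loglik(A, rcore, ccore, rdeg, cdeg, F)
                    ccore[i] = ~ccore[i]
                if cand > best[0] + 1e-10:
                    best = (cand, (side, i))
        if best[1] is not None:
            side, i = best[1]
            if side == "r":
                rcore[i] = ~rcore[i]
            else:
                ccore[i] = ~ccore[i]
            ll = best[0]
            improved = True
    return rcore, ccore, ll


def core_periphery(matrix: VisitationMatrix) -> CorePeriphery:
    """Split each guild into core/periphery and report the CPness statistic.

    The 2x2 block partition maximizes a Poisson block log-likelihood
    (one rate per block), searched by steepest-ascent flips from every
    weighted-degree threshold split of the two guilds (deterministic).
    The orientation with the denser within-block connectance is labelled
    core.  ``CPness = (E11 + E12 + E21) / F`` — the share of interaction
    weight touching the core.  A single-species guild is all-core by
    convention.
    """
    A = matrix.A
    F = matrix.F
    if F <= 0:
        raise ValueError("empty network")
    n_r, n_c = A.shape
    rdeg = A.sum(axis=1)
    cdeg = A.sum(axis=0)

    def threshold_splits(deg):
        order = np.argsort(-deg, kind="stable")
        splits = []
        for k in range(len(deg) + 1):
            f = np.zeros(len(deg), dtype=bool)
            f[order[:k]] = True
            splits.append(f)
        return splits

    best = (-np.inf, None, None)
    for r0 in threshold_splits(rdeg):
        for c0 in threshold_splits(cdeg):
            rcore, ccore, ll = _greedy_cp(A, rdeg, cdeg, F, r0, c0)
            if ll > best[0] + 1e-10:
                best = (ll, rcore, ccore)
    _, rcore, ccore = best

    def density(rmask, cmask):
        cells = rmask.sum() * cmask.sum()
        if cells == 0:
            return -1.0
        return A[np.ix_(rmask, cmask)].sum() / cells

    # orient so the denser within-block side is the core
    if density(~rcore, ~ccore) > density(rcore, ccore):
        rcore, ccore = ~rcore, ~ccore
    if n_r == 1:
        rcore = np.array([True])
    if n_c == 1:
        ccore = np.array([True])

    E11 = float(A[np.ix_(rcore, ccore)].sum())
    E12 = float(A[np.ix_(rcore, ~ccore)].sum())
    E21 = float(A[np.ix_(~rcore, ccore)].sum())
    E22 = float(A[np.ix_(~rcore, ~ccore)].sum())
    return CorePeriphery(
        row_core=pd.Series(rcore, index=matrix.row_labels, name="core"),
        col_core=pd.Series(ccore, index=matrix.col_labels, name="core"),
        E11=E11,
        E12=E12,
        E21=E21,
        E22=E22,
        cpness=(E11 + E12 + E21) / F,
    )
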