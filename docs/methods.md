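# Methods

This note documents the models, estimators and numerical choices in
`dominet`, what the synthetic generator does and does not emulate, and
the package's known limitations.

## Dominance ranking

**David's score.** For each dyad with at least one contest the win
proportion is `P_ij = W_ij / (W_ij + W_ji)`; dyads never observed
contesting contribute nothing to any sum. With `w_i = Σ_j P_ij`,
`w2_i = Σ_j P_ij w_j`, `l_i = Σ_j P_ji`, `l2_i = Σ_j P_ji l_j`, the score
is `Ds_i = w_i + w2_i − l_i − l2_i`. The zero-sum identity `Σ Ds = 0` is
algebraic and asserted to 1e-9 in tests; a brute-force implementation
that materializes every term with explicit loops is the test oracle.
Raw win proportions are used (no sample-size correction): the index was
designed for incomplete tournaments, and a corrected variant would be a
one-line change in `davids_score`.

**Dyadic probabilities with indirect pathways.** Published network-based
ranking methods in the percolation/conductance family pool direct
contests with transitive information through common third parties, but
their internals vary; `dominance_probabilities` is an explicit,
configurable reconstruction, not a claim of equivalence to any package.
The pooled flow is `F = W + Σ_{k=2..K} δ^{k−1} N_k`, where `N_k` counts
directed length-`k` walks in the binarized win-majority graph
(`B_ij = 1` iff `W_ij > W_ji`), with defaults `K = 2`, `δ = 0.5`.
Add-half smoothing `P_ij = (F_ij + 0.5)/(F_ij + F_ji + 1)` guarantees
`P + Pᵀ = 1` and places information-free dyads at exactly 0.5.

**Rank order and certainty.** The ordinal order maximizes
`Σ_{i before j} P_ij`. Search: seeded simulated annealing (geometric
cooling, factor 0.99, 400 steps, 10 restarts) followed by a
strict-improvement pairwise-swap hill climb; the identity order is the
first start, so a fully ambiguous matrix returns the input order (the
documented tie-break). Exactness at `n ≤ 6` is checked against
exhaustive permutation search. Certainty is
`DC_i = mean_{j≠i} max(P_ij, P_ji)` with its sample SD; species at
`DC ≤ 0.5` (typically those observed in no contests) are removed by
`filter_uncertain_species` and the reduced tournament re-ranked.

## Network statistics

**Specialization d′.** `d_i = Σ_j p'_ij ln(p'_ij / q_j)` with
`p'_ij = a_ij / r_i` and availability `q_j = c_j / F`. The extremes are
integer-unit constructions, since visit totals are counts: `d_min` from
a largest-remainder allocation of the row total proportional to `q`
(ties to the lower index), `d_max` from loading units one at a time onto
the partner that maximizes the summand (ties to the rarer partner) —
both oracle-tested against exhaustive enumeration over integer
compositions at small totals. `d' = (d − d_min)/(d_max − d_min)`,
clamped to [0, 1]; degenerate rows (`d_max = d_min`) report 0, zero rows
report NaN and are excluded from regressions. d′ is computed on raw
counts; interaction-frequency weighting is an option of the regression
stage, not of d′ itself.

**Modularity.** Barber's weighted bipartite
`Q = (1/F) Σ (a_ij − r_i c_j / F)[g_i = h_j]`. The maximizer follows the
DIRTLPAwb+ recipe: per run, initialize column labels with a
run-dependent number of random modules (run 0: every column its own
module), alternate best-label propagation between guilds until Q stops
improving, then interleave strict-improvement module merges with further
propagation; keep the best of `n_runs` (default 50, the study's setting)
runs, deterministic given the seed. The source description of the
algorithm this emulates mentions an MCMC step budget that does not apply
to a label-propagation scheme; the iteration budget here is simply
"until no improvement", which terminates because Q strictly increases.
Self-consistency (returned Q equals `barber_modularity` recomputed on
the returned labels) is asserted to 1e-12.

**Null model and z-score.** `patefield_sample` draws uniformly from
count tables with fixed margins by filling rows with multivariate
hypergeometric draws against the remaining column totals; margins are
conserved exactly on every draw and the 2×2 enumeration frequencies are
tested. The z-score uses `n_null = 100` replicates (study setting), each
optimized with the same `n_runs` budget as the observed network so the
comparison is not biased by asymmetric search effort. A zero-spread null
ensemble reports ±inf with a warning.

**Core–periphery.** Each guild is split core/periphery to maximize a
plain Poisson 2×2-block log-likelihood
`Σ_b e_b ln(e_b/n_b) − e_b` (block weight `e_b`, cells `n_b`,
`0 ln 0 = 0`). The objective is deliberately *not* degree-corrected:
core–periphery structure is a degree phenomenon, and a degree-corrected
objective absorbs exactly the signal being sought (it is indifferent to
moving a zero-degree species between blocks and can even prefer
splitting a uniform dense block). Search is steepest-ascent single-species
flips from every weighted-degree threshold split of both guilds —
deterministic, and exact on 4×4 fixtures against exhaustive search over
all `2^(r+c)` assignments. The orientation with the denser within-block
connectance is labelled core; a single-species guild is all-core by
convention. `CPness = (E11 + E12 + E21)/F`.

## Interaction-frequency GAM

The pair table is the full factorial (every hummingbird × plant pair,
structural zeros retained as response 0 — a pairwise frequency model
needs the unrealized pairs, and this is flagged as an assumption).
Predictors: abundance proportions of both guilds, calories per flower
(`µL × molarity × 1.34`; Brix→molarity uses the dilute-sucrose
approximation `Brix × 10 / 342.3` and is isolated in
`brix_to_molarity`), calories per plant species (per flower × flower
count), morphological match (Euclidean distance of the four z-scored
bill/corolla variables; zero-variance traits z-score to 0 with a
warning), corolla length, bill length, weight, and David's score.

The model is a negative-binomial GAM (log link, variance
`µ + µ²/θ`) with one univariate penalized cubic B-spline per predictor
(basis size 10, second-derivative penalty; the basis backbone is
statsmodels' `GLMGam`/`BSplines`). Smoothing parameters are selected by
coordinate descent over a log-spaced grid (10⁻² … 10⁶, two sweeps)
minimizing `GCV_γ = n·D / (n − γ·edf)²` with γ = 1.4 — the
heavier-than-nominal cost per effective degree of freedom that guards
against overfitting. θ is estimated by outer likelihood maximization
(bounded scalar search on log θ) around the selected smoothing
parameters; pass `theta=` to fix it.

Per-smooth inference is a rank-truncated Wald test: the chi-square
statistic uses only the top `ceil(edf)` eigen-directions of the smooth's
coefficient covariance, with df equal to that rank. A naive full-rank
pseudo-inverse Wald with df = edf proved anti-conservative in the size
simulation (heavily penalized directions contribute noise); the
truncated version achieves ~4% size at nominal 5% with full power in the
50-replicate neutral simulation. Three caveats are worth stating. First,
`Σ fitted = Σ observed` holds exactly only in the Poisson limit — the NB
intercept score weights residuals by `1/(1 + µ/θ)` — so total
conservation is approximate at finite θ (tested at 0.1% for the Poisson
limit). Second, identifiability handling can leave a strongly penalized
smooth's edf marginally below 1; values are reported as computed, with
edf ≈ 1 still reading "effectively linear". Third, species-level
predictors in a pair-level design are pseudo-replicated (13 values
repeated over 10 plants each); the size simulation uses a pair-level
noise predictor precisely because a species-level one genuinely (not
spuriously) soaks up residual species effects — interpret per-smooth
p-values for species-level traits with that in mind.

## PCA and regressions

PCA is an eigen-decomposition of the correlation matrix (covariance if
`standardize=False`); axes ordered by decreasing eigenvalue, sign fixed
so each axis's largest-magnitude loading is positive, per-variable
contributions `100 × loading²` (summing to 100 per axis). Constant
columns are an error naming the column. Regressions are OLS by default;
the square-root-of-total-visits weighting used in some specialization
analyses is available via `weights`, off by default because where the
weighting should enter is genuinely ambiguous. F is reported with
`df2 = n − 2` (the df printed in some source tables is internally
inconsistent with the stated sample size; R², which is df-free, is
always echoed for comparison).

## Synthetic communities

Defaults are the study conditions of the emulated system: 13 hummingbird
and 10 plant species, 477 contests, 2,272 visits, dyad observability
0.45 (which with contest-free observable dyads yields ≈0.55 of dyads
unknown), logistic (Bradley–Terry) contest outcomes with steepness 2 in
standard-normal latent scores, lognormal species-abundance
distributions, and interaction-driver mixture weights 0.7 neutrality /
0.15 trait matching / 0.15 dominance preference — an
abundance-dominated community. The dominance driver is a softmax over
standardized plant calories whose sharpness decays linearly with rank
index, encoding "dominants monopolize energy-rich plants" in one knob.
All sub-streams derive from one integer seed; identical seed and
parameters give bit-identical outputs.

Parameter-recovery experiments use a well-sampled variant
(observability 0.8) because rank recovery is limited by structurally
missing dyads rather than by the estimator; the recovery property
(Spearman of Ds against latent scores ≥ 0.9 over 50 seeds) is part of
the acceptance suite.

What the generator does **not** emulate: temporal phenology and
turnover, spatial foraging structure, individual-level variation,
observation effort biases, and trait–abundance covariances beyond the
built-in bill/weight–dominance link. Passing tests therefore show the
estimators recover known structure under idealized sampling — not that
field data meet these assumptions.

## Problem sizes and determinism

Default budgets (50 modularity restarts, 100 null replicates, 10
annealing restarts) are the study's analysis settings and run in seconds
at the 13 × 10 scale. Simulation-based tests use 20–50 seeds and
reduced search budgets chosen so the full suite runs in a few minutes;
the properties tested are budget-robust (they also hold at larger
budgets). Every stochastic routine takes an explicit seed and is
bit-reproducible; ties are broken deterministically (input order for
ranks, lower index for allocations, first-best for searches).

## Limitations

- The indirect-pathway dominance probabilities are a documented
  reconstruction of a method family, not a re-implementation of any
  specific published package; DC values are comparable within this
  package, not across implementations.
- d′ extremes use integer-unit heuristics (oracle-exact at small
  totals); other packages' extremal conventions can differ, shifting d′
  by a constant rescaling per row.
- The GAM's GCV-γ selection is a pragmatic grid/coordinate scheme; it
  is not guaranteed to find the global optimum of the joint smoothing
  surface, though the selected fits are stable across sweeps in
  practice.
- Nestedness, network-level H2′ and robustness analyses are out of
  scope by design.
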