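# dominet

Dominance hierarchies and the structure of quantitative plant–pollinator
networks, in one tested Python package.

Territorial nectarivores — hummingbirds are the canonical case — compete
aggressively for flower patches, and a community's dominance hierarchy can
shape who visits what. `dominet` links the two data streams such studies
produce:

1. an **agonistic matrix** `W` (`W[i, j]` = contests species *i* won
   against *j*, usually with many never-observed dyads), and
2. a **quantitative visitation matrix** `A` (`a_ij` = visits of
   hummingbird *i* to plant *j*), plus species-level trait, nectar and
   abundance tables.

## What it computes

**Dominance** — David's score
`Ds_i = w_i + w2_i − l_i − l2_i`, where `w_i = Σ_j P_ij` is the sum of
*i*'s dyadic win proportions, `w2_i = Σ_j P_ij w_j` weighs the records of
its victims, and `l`, `l2` are the mirror loss terms; scores sum to zero
and tolerate incomplete tournaments. Alongside it, a network-based
ranking: dyadic dominance probabilities that pool direct contests with
indirect win pathways through third parties, an ordinal order maximizing
`Σ_{i<j} P_ij` (seeded simulated annealing, exact at small n), and a
dominance certainty `DC_i = mean_j max(P_ij, P_ji) ∈ [0.5, 1]` used to
drop species whose position the data cannot resolve.

**Network structure** — per-species specialization
`d'_i = (d_i − d_min)/(d_max − d_min)` with
`d_i = Σ_j p'_ij ln(p'_ij/q_j)` (Kullback–Leibler divergence of partner
use `p'` from availability `q`); weighted bipartite (Barber) modularity
`Q = (1/F) Σ_ij (a_ij − r_i c_j/F)·[g_i = h_j]`, maximized by a
restart-wrapped label-propagation + merge search (DIRTLPAwb+ family) and
tested against a fixed-margins (Patefield) null ensemble via
`z = (Q_obs − mean Q_null)/sd Q_null`; and a 2×2 core–periphery split
with `CPness = (E11 + E12 + E21)/F`.

**Interaction frequency** — a negative-binomial GAM of pair-level visit
counts (structural zeros included) on abundance proportions, nectar
energetics (`calories = µL × mol × 1.34`, Brix→molarity isolated in one
function), morphological match (Euclidean distance of z-scored
bill/corolla length and curvature), weight and dominance; one penalized
cubic spline per predictor, smoothness chosen by GCV with each effective
degree of freedom costing γ = 1.4, dispersion θ by outer likelihood
maximization.

**Closing statistics** — correlation-matrix PCA of trait/dominance
spaces with per-variable contributions, and (optionally weighted) linear
regressions of `d'` on dominance and bill morphology.

A first-class synthetic generator (`SyntheticScenario`) supplies
communities with known ground truth — latent dominance scores with
Bradley–Terry contest outcomes, and visit distributions mixing
neutrality (abundance products), trait matching and dominance-driven
preference for calorie-rich plants — so every estimator is validated by
parameter recovery.

## Worked example

```python
import dominet as dn

scenario = dn.SyntheticScenario(seed=0)   # 13 x 10 species, 477 contests, 2272 visits
W = dn.simulate_tournament(scenario)
s = dn.tournament_summary(W)
# -> 477 contests among 13 species: 36.7 per species, 6.1 per dyad

traits = dn.simulate_traits(scenario)
V = dn.simulate_visitation(scenario, traits)
part = dn.modularity_zscore(V, n_null=100, n_runs=50, seed=0)
# -> Q = 0.078 (4 modules); null mean 0.050 +/- 0.005, z = 6.2
```

`36.7` and `6.1` are the tournament's sampling intensities (contests per
species and per unordered species pair). `Q = 0.078` says module
structure in this abundance-dominated community is weak, but `z = 6.2`
says it is still far beyond what the row/column totals alone produce.
Fitting the interaction GAM on the same community
(`examples/03_interaction_gam.py`) gives

```
                              edf  chi_square  p_value
morph_match                 1.379       7.924    0.019
flower_abundance_prop       0.954      11.994    0.001
hummingbird_abundance_prop  1.463     155.011    0.000
...
deviance explained = 88.4%
```

— the abundance smooths dominate, exactly the neutrality structure the
generator planted. The `examples/` scripts walk through each capability
(dominance ranking, network structure, the GAM, the full pipeline); a
thin CLI wraps the same calls
(`dominet simulate|dominance|network|gam|reproduce`).

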