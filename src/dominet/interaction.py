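"""Pairwise interaction-frequency model: predictors and negative-binomial GAM.

Builds the full factorial hummingbird x plant pair table — visit counts
(including structural zeros) plus the ecological predictors: abundance
proportions of both partners, nectar energetics (calories per flower and
per plant species), morphological trait match, raw morphology, body weight
and dominance score — and fits a negative-binomial generalized additive
model with one univariate penalized spline per predictor.  Smoothing
parameters are chosen by generalized cross-validation with an inflated
per-degree-of-freedom cost (gamma) to damp overfitting; the dispersion
parameter is estimated by outer likelihood maximization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg, optimize, stats
from statsmodels.gam.api import BSplines, GLMGam

from dominet.network import VisitationMatrix

__all__ = [
    "TraitTable",
    "GAMFit",
    "brix_to_molarity",
    "calories_per_flower",
    "calories_per_species",
    "morphological_match",
    "abundance_proportions",
    "build_pair_table",
    "fit_nb_gam",
    "DEFAULT_PREDICTORS",
]

SUCROSE_MOLAR_MASS = 342.3  # g/mol

HB_COLUMNS = ["bill_length", "bill_curvature", "weight", "abundance"]
PL_COLUMNS = [
    "corolla_length",
    "corolla_diameter",
    "corolla_curvature",
    "nectar_volume",
    "nectar_concentration",
    "flower_abundance",
]

DEFAULT_PREDICTORS = [
    "morph_match",
    "flower_abundance_prop",
    "hummingbird_abundance_prop",
    "calories_per_flower",
    "calories_per_species",
    "corolla_length",
    "bill_length",
    "weight",
    "Ds",
]


@dataclass
class TraitTable:
    """Species-level traits: one table per guild, indexed by species label.

    Hummingbirds: bill length (mm), bill curvature (deg), weight (g),
    abundance (survey counts), optionally a dominance score ``Ds``.
    Plants: corolla length/diameter (mm), corolla curvature (deg), nectar
    volume (uL), nectar concentration (degrees Brix), flower abundance
    (transect counts).
    """

    hummingbirds: pd.DataFrame
    plants: pd.DataFrame

    def __post_init__(self) -> None:
        for df, cols, name in (
            (self.hummingbirds, HB_COLUMNS, "hummingbird"),
            (self.plants, PL_COLUMNS, "plant"),
        ):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise ValueError(f"{name} trait table missing columns: {missing}")
            if df.index.has_duplicates:
                raise ValueError(f"duplicate species in {name} trait table")
        for col in ("bill_curvature",):
            v = self.hummingbirds[col]
            if ((v < 0) | (v > 90)).any():
                raise ValueError(f"{col} must lie in [0, 90] degrees")
        if ((self.plants["corolla_curvature"] < 0) | (self.plants["corolla_curvature"] > 90)).any():
            raise ValueError("corolla_curvature must lie in [0, 90] degrees")
        for name, df in (("hummingbird", self.hummingbirds), ("plant", self.plants)):
            nonneg = [c for c in df.columns if c != "Ds"]
            if (df[nonneg] < 0).any().any():
                raise ValueError(f"negative values in {name} trait table")

    def with_calories(self) -> "TraitTable":
        """Return a copy whose plant table carries derived calorie columns."""
        pl = self.plants.copy()
        pl["calories_per_flower"] = calories_per_flower(
            pl["nectar_volume"].to_numpy(), pl["nectar_concentration"].to_numpy()
        )
        pl["calories_per_species"] = calories_per_species(
            pl["calories_per_flower"].to_numpy(), pl["flower_abundance"].to_numpy()
        )
        return TraitTable(self.hummingbirds, pl)


@dataclass
class GAMFit:
    """Negative-binomial GAM fit summary (per-smooth table + global stats)."""

    smooth_table: pd.DataFrame  # index: predictor; columns: edf, chi_square, p_value
    theta: float
    deviance_explained: float
    r2_adj: float
    fitted: pd.Series
    alphas: dict[str, float]
    edf_total: float
    deviance: float
    null_deviance: float


def brix_to_molarity(brix: np.ndarray | float) -> np.ndarray | float:
    """Degrees Brix (g sucrose / 100 g solution) to mol/L of sucrose.

    Uses the dilute-solution approximation ``Brix * 10 / 342.3``
    (grams per litre divided by the molar mass of sucrose).  Isolated here
    so an alternative conversion is a one-line change.
    """
    b = np.asarray(brix, dtype=float)
    if np.any(b < 0):
        raise ValueError("Brix cannot be negative")
    out = b * 10.0 / SUCROSE_MOLAR_MASS
    return float(out) if np.isscalar(brix) else out


def calories_per_flower(
    volume_ul: np.ndarray | float,
    concentration_brix: np.ndarray | float | None = None,
    molarity: np.ndarray | float | None = None,
) -> np.ndarray | float:
    """Nectar energy per flower: volume (uL) x sugar molarity (mol/L) x 1.34.

    Pass the refractometer reading as ``concentration_brix`` (converted to
    molarity via :func:`brix_to_molarity`) or the molarity directly.
    Readings outside the 0-32 Brix refractometer range trigger a warning.
    """
    v = np.asarray(volume_ul, dtype=float)
    if np.any(v < 0):
        raise ValueError("nectar volume cannot be negative")
    if (concentration_brix is None) == (molarity is None):
        raise ValueError("give exactly one of concentration_brix or molarity")
    if molarity is None:
        b = np.asarray(concentration_brix, dtype=float)
        if np.any(b > 32):
            warnings.warn("Brix reading above the 0-32 refractometer range")
        m = brix_to_molarity(b)
    else:
        m = np.asarray(molarity, dtype=float)
        if np.any(m < 0):
            raise ValueError("molarity cannot be negative")
    out = v * m * 1.34
    return float(out) if np.isscalar(volume_ul) else np.asarray(out)


def calories_per_species(
    cal_per_flower: np.ndarray | float, total_flowers: np.ndarray | float
) -> np.ndarray | float:
    """Energy standing crop of a plant species: calories/flower x flower count."""
    c = np.asarray(cal_per_flower, dtype=float)
    f = np.asarray(total_flowers, dtype=float)
    if np.any(c < 0) or np.any(f < 0):
        raise ValueError("inputs must be nonnegative")
    out = c * f
    return float(out) if np.isscalar(cal_per_flower) and np.isscalar(total_flowers) else out


def _zscore(x: pd.Series) -> np.ndarray:
    v = x.to_numpy(dtype=float)
    sd = v.std(ddof=0)
    if sd == 0:
        warnings.warn(f"trait {x.name!r} has zero variance; z-scores set to 0")
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def morphological_match(
    hb_traits: pd.DataFrame, pl_traits: pd.DataFrame
) -> pd.DataFrame:
    """Bill-corolla mismatch as Euclidean distance in standardized traits.

    Bill length pairs with corolla length and bill curvature with corolla
    curvature; each of the four variables is z-scored over its own guild.
    Larger values mean a worse morphological match.
    """
    for col in ("bill_length", "bill_curvature"):
        if col not in hb_traits.columns:
            raise ValueError(f"hummingbird traits missing {col!r}")
    for col in ("corolla_length", "corolla_curvature"):
        if col not in pl_traits.columns:
            raise ValueError(f"plant traits missing {col!r}")
    zbl = _zscore(hb_traits["bill_length"])
    zbc = _zscore(hb_traits["bill_curvature"])
    zcl = _zscore(pl_traits["corolla_length"])
    zcc = _zscore(pl_traits["corolla_curvature"])
    d = np.sqrt(
        (zbl[:, None] - zcl[None, :]) ** 2 + (zbc[:, None] - zcc[None, :]) ** 2
    )
    return pd.DataFrame(d, index=hb_traits.index, columns=pl_traits.index)


def abundance_proportions(counts) -> pd.Series | np.ndarray:
    """Relative abundance per species from survey counts.

    Accepts a vector of per-species totals or a species x survey table
    (summed over surveys); returns proportions summing to 1.
    """
    if isinstance(counts, pd.DataFrame):
        totals = counts.sum(axis=1)
    else:
        totals = pd.Series(np.asarray(counts, dtype=float)) if not isinstance(
            counts, pd.Series
        ) else counts.astype(float)
    if (totals < 0).any():
        raise ValueError("counts must be nonnegative")
    grand = totals.sum()
    if grand <= 0:
        raise ValueError("at least one species count must be positive")
    out = totals / grand
    return out


def build_pair_table(visits: VisitationMatrix, traits: TraitTable) -> pd.DataFrame:
    """Full factorial pair table: one record per hummingbird x plant pair.

    Structural zeros are retained (visits = 0 for unobserved pairs), so the
    table always has ``n_hummingbirds * n_plants`` rows and the visit
    column sums to the matrix grand total.
    """
    hb = traits.hummingbirds
    pl = traits.with_calories().plants
    missing_hb = [s for s in visits.row_labels if s not in hb.index]
    missing_pl = [s for s in visits.col_labels if s not in pl.index]
    if missing_hb or missing_pl:
        raise ValueError(
            f"species missing from trait tables: hummingbirds {missing_hb}, "
            f"plants {missing_pl}"
        )
    if "Ds" not in hb.columns:
        raise ValueError("hummingbird trait table needs a 'Ds' column "
                         "(compute it with dominet.dominance.davids_score)")
    hb = hb.loc[visits.row_labels]
    pl = pl.loc[visits.col_labels]
    match = morphological_match(hb, pl)
    hb_prop = abundance_proportions(hb["abundance"])
    fl_prop = abundance_proportions(pl["flower_abundance"])

    records = []
    for i, h in enumerate(visits.row_labels):
        for j, p in enumerate(visits.col_labels):
            records.append(
                {
                    "hummingbird": h,
                    "plant": p,
                    "visits": visits.A[i, j],
                    "morph_match": match.iloc[i, j],
                    "flower_abundance_prop": fl_prop[p],
                    "hummingbird_abundance_prop": hb_prop[h],
                    "calories_per_flower": pl.loc[p, "calories_per_flower"],
                    "calories_per_species": pl.loc[p, "calories_per_species"],
                    "corolla_length": pl.loc[p, "corolla_length"],
                    "bill_length": hb.loc[h, "bill_length"],
                    "weight": hb.loc[h, "weight"],
                    "Ds": hb.loc[h, "Ds"],
                }
            )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# negative-binomial GAM
# ---------------------------------------------------------------------------


def _gam_model(y, X_smooth, names, basis_size, alpha, theta):
    df = [min(basis_size, max(4, len(np.unique(col)) - 1)) for col in X_smooth.T]
    bs = BSplines(
        X_smooth, df=df, degree=[3] * X_smooth.shape[1], variable_names=list(names)
    )
    fam = sm.families.NegativeBinomial(alpha=1.0 / theta)
    model = GLMGam(
        y, np.ones((len(y), 1)), smoother=bs, family=fam, alpha=list(alpha)
    )
    return model, bs


def _fit(y, X_smooth, names, basis_size, alpha, theta):
    model, bs = _gam_model(y, X_smooth, names, basis_size, alpha, theta)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=200)
    return res, bs


def _gcv(res, gamma):
    n = res.nobs
    edf = res.edf.sum()
    denom = max(n - gamma * edf, 1e-8)
    return n * res.deviance / denom**2


def _nb_loglik(y, mu, theta):
    r = theta
    p = r / (r + mu)
    return float(stats.nbinom.logpmf(y, r, p).sum())


def fit_nb_gam(
    table: pd.DataFrame,
    predictors: list[str] | None = None,
    gamma: float = 1.4,
    basis_size: int = 10,
    theta: float | None = None,
    alphas: dict[str, float] | None = None,
    response: str = "visits",
) -> GAMFit:
    """Negative-binomial GAM of pair-level visit counts.

    One penalized univariate cubic B-spline smooth per predictor
    (``basis_size`` basis functions, second-derivative penalty), log link.
    Smoothing parameters are selected by coordinate-descent generalized
    cross-validation in which each effective degree of freedom costs
    ``gamma`` (default 1.4) — the heavier-than-nominal per-df penalty that
    guards against overfitting.  The dispersion ``theta`` (variance
    ``mu + mu^2/theta``) is estimated by outer likelihood maximization
    unless supplied.  Reports per-smooth effective degrees of freedom, a
    Wald chi-square against the zero function, deviance explained and
    adjusted R^2.
    """
    if predictors is None:
        predictors = [c for c in DEFAULT_PREDICTORS if c in table.columns]
    if not predictors:
        raise ValueError("no predictors available")
    if len(table) < 30:
        raise ValueError("need at least 30 pair records to fit the GAM")
    y = table[response].to_numpy(dtype=float)
    if np.any(y < 0) or np.any(np.abs(y - np.round(y)) > 1e-9):
        raise ValueError("response must be nonnegative integer counts")
    y = np.round(y).astype(int)
    X = table[predictors].to_numpy(dtype=float)
    if np.any(~np.isfinite(X)):
        raise ValueError("non-finite predictor values")
    p = len(predictors)

    # initial dispersion: Pearson moment estimate from a mildly smoothed fit
    if theta is None:
        res0, _ = _fit(y, X, predictors, basis_size, [1.0] * p, 10.0)
        mu0 = np.clip(res0.fittedvalues, 1e-8, None)
        a0 = max(float(np.sum((y - mu0) ** 2 - mu0) / np.sum(mu0**2)), 1e-3)
        theta_hat = 1.0 / a0
    else:
        theta_hat = float(theta)

    # smoothing parameters: coordinate descent on a log-spaced grid
    if alphas is None:
        grid = 10.0 ** np.arange(-2.0, 6.1, 1.0)
        cur = np.full(p, 10.0)
        for _sweep in range(2):
            for k in range(p):
                best_val, best_a = np.inf, cur[k]
                for a in grid:
                    trial = cur.copy()
                    trial[k] = a
                    try:
                        res, _ = _fit(y, X, predictors, basis_size, trial, theta_hat)
                    except (linalg.LinAlgError, ValueError):
                        continue
                    val = _gcv(res, gamma)
                    if val < best_val - 1e-12:
                        best_val, best_a = val, a
                cur[k] = best_a
        alpha_vec = cur
    else:
        alpha_vec = np.array([alphas[name] for name in predictors], dtype=float)

    # outer likelihood maximization for the dispersion
    if theta is None:
        def neg_ll(log_t):
            t = float(np.exp(log_t))
            try:
                res, _ = _fit(y, X, predictors, basis_size, alpha_vec, t)
            except (linalg.LinAlgError, ValueError):
                return np.inf
            return -_nb_loglik(y, np.clip(res.fittedvalues, 1e-8, None), t)

        opt = optimize.minimize_scalar(
            neg_ll, bounds=(np.log(1e-2), np.log(1e4)), method="bounded",
            options={"xatol": 1e-2},
        )
        theta_hat = float(np.exp(opt.x))

    res, bs = _fit(y, X, predictors, basis_size, alpha_vec, theta_hat)
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError("GAM failed to converge: non-finite coefficients")

    # per-smooth edf and rank-truncated Wald chi-square: testing only the
    # effectively-free directions (rank ~ ceil(edf)) keeps the test from
    # counting heavily penalized coefficient directions as evidence
    cov = np.asarray(res.cov_params())
    params = np.asarray(res.params)
    edf_all = np.asarray(res.edf)
    offset = 1  # intercept column
    rows = []
    for k, name in enumerate(predictors):
        dim = bs.smoothers[k].dim_basis
        sl = slice(offset, offset + dim)
        edf_k = float(edf_all[sl].sum())
        beta = params[sl]
        Vk = cov[sl, sl]
        ev, U = np.linalg.eigh(Vk)
        order = np.argsort(ev)[::-1]
        ev, U = ev[order], U[:, order]
        rank = int(min(dim, max(1, np.ceil(edf_k))))
        proj = U.T @ beta
        chi2 = float(np.sum(proj[:rank] ** 2 / np.maximum(ev[:rank], 1e-12)))
        pval = float(stats.chi2.sf(chi2, rank))
        rows.append((name, edf_k, chi2, pval))
        offset += dim
    smooth_table = pd.DataFrame(
        rows, columns=["predictor", "edf", "chi_square", "p_value"]
    ).set_index("predictor")

    dev_expl = 100.0 * (1.0 - res.deviance / res.null_deviance)
    fitted = np.asarray(res.fittedvalues)
    edf_tot = float(edf_all.sum())
    rss = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2_adj = 1.0 - (rss / max(len(y) - edf_tot, 1.0)) / (tss / (len(y) - 1))
    return GAMFit(
        smooth_table=smooth_table,
        theta=theta_hat,
        deviance_explained=float(dev_expl),
        r2_adj=float(r2_adj),
        fitted=pd.Series(fitted, index=table.index, name="fitted"),
        alphas=dict(zip(predictors, alpha_vec)),
        edf_total=edf_tot,
        deviance=float(res.deviance),
        null_deviance=float(res.null_deviance),
    )
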