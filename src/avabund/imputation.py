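"""Two-level chained-equations imputation with predictive mean matching.

The imputation table has one row per species x grid cell, with exactly
eleven variables: the species id (the clustering factor), three
always-complete effort/abundance covariates, five species-level traits,
and the two targets (log10 density and its SE, missing together for all
non-training species).  Species-level variables are imputed once per
species from a cluster-aggregated regression; observation-level variables
are imputed from a random-intercept linear mixed model.  Both use
predictive mean matching (PMM): an imputed cell always receives the
observed value of a donor row with a nearby model-predicted mean, so
imputations never extrapolate beyond observed values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import as_rng, spawn_rngs
from .regression import predict_log_density

ID_COLUMN = "species_id"
COMPLETE_COLUMNS = ["log_n_checklists", "n_months_observed", "rel_abund"]
SPECIES_LEVEL = ["flock_size", "iucn_ordinal", "body_mass",
                 "dist_from_brown", "brightness"]
OBSERVATION_LEVEL = ["density_log10", "density_se"]
ALL_COLUMNS = [ID_COLUMN] + COMPLETE_COLUMNS + SPECIES_LEVEL + OBSERVATION_LEVEL


def assemble_imputation_table(
    relabund_records: pd.DataFrame,
    traits: pd.DataFrame,
    coefficients: pd.DataFrame | None,
    rho: float = -1.0,
) -> pd.DataFrame:
    """Build the 11-variable species x grid table.

    Density and its SE are filled only for species present in
    ``coefficients`` (the training species), via the per-species linear
    predictor at the row's log10 relative abundance with slope–intercept
    error correlation ``rho``; all other rows have both missing.
    """
    if relabund_records.duplicated([ID_COLUMN, "grid_id"]).any():
        raise ValueError("duplicate species x grid rows")
    tab = relabund_records.copy()
    tr = traits.rename(columns={"body_mass_g": "body_mass"})
    tab = tab.merge(tr[[ID_COLUMN] + SPECIES_LEVEL], on=ID_COLUMN, how="left")
    tab["density_log10"] = np.nan
    tab["density_se"] = np.nan
    if coefficients is not None and len(coefficients):
        coef = coefficients.set_index(ID_COLUMN)
        is_train = tab[ID_COLUMN].isin(coef.index)
        sub = tab.loc[is_train]
        x = np.log10(sub["rel_abund"].to_numpy())
        c = coef.loc[sub[ID_COLUMN]]
        mean, se = predict_log_density(c, x, rho=rho)
        tab.loc[is_train, "density_log10"] = mean
        tab.loc[is_train, "density_se"] = se
    cols = [ID_COLUMN, "grid_id"] + COMPLETE_COLUMNS + SPECIES_LEVEL \
        + OBSERVATION_LEVEL
    return tab[cols].reset_index(drop=True)


def missing_fractions(table: pd.DataFrame) -> pd.Series:
    return table.drop(columns=[ID_COLUMN]).isna().mean()


# ----------------------------------------------------------------------
# random-intercept linear model (moment-based, one clustering factor)

@dataclass
class _REFit:
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2_e: float
    sigma2_u: float
    blup: np.ndarray  # per-group random intercepts
    df: int
    sse: float
    observed_groups: np.ndarray = None  # bool: group has >=1 observed row


def fit_random_intercept(y: np.ndarray, X: np.ndarray, codes: np.ndarray,
                         n_groups: int) -> _REFit:
    """GLS fit of y = X beta + u_group + e with moment variance components.

    Variance components come from the OLS residuals (within-group scatter
    for sigma_e^2, shrunken between-group scatter for sigma_u^2); the GLS
    step quasi-demeans by group.  Fast, deterministic, and adequate for
    the predicted means PMM needs.
    """
    n, p = X.shape
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    e = y - X @ beta_ols
    n_g = np.bincount(codes, minlength=n_groups).astype(float)
    present = n_g > 0
    ebar = np.zeros(n_groups)
    np.add.at(ebar, codes, e)
    ebar[present] /= n_g[present]
    within = e - ebar[codes]
    df_within = n - int(present.sum()) - (p - 1)
    if df_within >= 1 and float(within @ within) > 1e-12:
        sigma2_e = float(within @ within) / df_within
        if present.sum() > 1:
            var_between = float(np.var(ebar[present], ddof=1))
            sigma2_u = max(0.0, var_between
                           - sigma2_e * float(np.mean(1.0 / n_g[present])))
        else:
            sigma2_u = 0.0
    else:
        # all-singleton (or degenerate) clusters: plain OLS, no random effect
        sigma2_e = max(float(e @ e) / max(1, n - p), 1e-12)
        sigma2_u = 0.0

    lam = np.zeros(n_groups)
    lam[present] = 1.0 - np.sqrt(sigma2_e / (sigma2_e + n_g[present] * sigma2_u)) \
        if sigma2_u > 0 else 0.0
    w = lam[codes]
    ybar = np.zeros(n_groups)
    np.add.at(ybar, codes, y)
    ybar[present] /= n_g[present]
    Xbar = np.zeros((n_groups, p))
    np.add.at(Xbar, codes, X)
    Xbar[present] /= n_g[present, None]
    yt = y - w * ybar[codes]
    Xt = X - w[:, None] * Xbar[codes]
    XtX = Xt.T @ Xt
    XtX += 1e-10 * np.eye(p)
    beta = np.linalg.solve(XtX, Xt.T @ yt)
    resid_t = yt - Xt @ beta
    df = max(1, n - p)
    sse = float(resid_t @ resid_t)
    cov_beta = sigma2_e * np.linalg.inv(XtX)

    shrink = np.zeros(n_groups)
    if sigma2_u > 0:
        shrink[present] = (n_g[present] * sigma2_u
                           / (sigma2_e + n_g[present] * sigma2_u))
    resid = y - X @ beta
    rbar = np.zeros(n_groups)
    np.add.at(rbar, codes, resid)
    rbar[present] /= n_g[present]
    blup = shrink * rbar
    return _REFit(beta, cov_beta, sigma2_e, sigma2_u, blup, df, sse, present)


def marginal_r2(y: np.ndarray, X: np.ndarray, codes: np.ndarray,
                n_groups: int) -> float:
    """Marginal R^2: fixed-effect variance over total (fixed + u + e)."""
    fit = fit_random_intercept(y, X, codes, n_groups)
    var_f = float(np.var(X @ fit.beta))
    return var_f / (var_f + fit.sigma2_u + fit.sigma2_e)


# ----------------------------------------------------------------------
# predictive mean matching

def _draw_mvn(rng, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """MVN draw via jittered Cholesky (cov may be near-singular)."""
    cov = 0.5 * (cov + cov.T)
    jitter = 1e-10 * max(1.0, float(np.trace(cov)))
    L = np.linalg.cholesky(cov + jitter * np.eye(len(mean)))
    return mean + L @ rng.standard_normal(len(mean))


def _pmm_match(pred_obs: np.ndarray, pred_mis: np.ndarray, y_obs: np.ndarray,
               donors: int, rng) -> np.ndarray:
    """For each missing cell pick one of the ``donors`` nearest observed."""
    k = min(donors, pred_obs.size)
    out = np.empty(pred_mis.size)
    for i, pm in enumerate(pred_mis):
        d = np.abs(pred_obs - pm)
        idx = np.argpartition(d, k - 1)[:k]
        out[i] = y_obs[idx[rng.integers(k)]]
    return out


#: columns that enter PMM design matrices on the log10 scale (they span
#: orders of magnitude; the density relation is log-linear)
LOG_SCALE_COLUMNS = ("rel_abund", "body_mass", "flock_size")


def _design_values(table: pd.DataFrame, columns: list[str],
                   log_columns) -> np.ndarray:
    """Predictor matrix with log10 transforms for the named skewed columns."""
    mat = table[columns].to_numpy(dtype=float).copy()
    for j, c in enumerate(columns):
        if c in log_columns:
            mat[:, j] = np.log10(np.maximum(mat[:, j], 1e-12))
    return mat


def _design_matrix(mat: np.ndarray) -> np.ndarray:
    """Intercept + z-standardized predictors, near-constant columns dropped.

    Standardizing and removing (near-)constant columns keeps the Bayesian
    coefficient perturbation well conditioned; a constant predictor is
    collinear with the intercept and its perturbed coefficient would shift
    every predicted mean by an arbitrary amount.
    """
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0)
    keep = sd > 1e-8
    z = (mat[:, keep] - mu[keep]) / sd[keep]
    return np.column_stack([np.ones(mat.shape[0]), z])


def pmm_draw(
    table: pd.DataFrame,
    target_column: str,
    predictors: list[str],
    level: str = "observation",
    donors: int = 5,
    seed=None,
    perturb: bool = True,
    cluster_col: str = ID_COLUMN,
    log_columns=LOG_SCALE_COLUMNS,
) -> pd.Series:
    """One PMM imputation of a single column; returns the completed column.

    Observation level: a random-intercept mixed model on observed rows;
    predicted means for missing rows use a Bayesian draw of the
    coefficients (``perturb``) so repeated imputations vary.  Species
    level: a species-level regression on cluster aggregates; one value is
    imputed per species and broadcast to its rows.

    Columns named in ``log_columns`` (predictors or the target itself)
    enter the linear model on the log10 scale; PMM still copies observed
    values on the original scale, so no back-transform bias is introduced.
    """
    rng = as_rng(seed)
    y_full = table[target_column].to_numpy(dtype=float)
    if target_column in log_columns:
        y_model = np.log10(np.maximum(y_full, 1e-12))
    else:
        y_model = y_full
    miss = np.isnan(y_full)
    if not miss.any():
        return table[target_column].copy()
    groups, codes = np.unique(table[cluster_col].to_numpy(), return_inverse=True)

    if level == "species":
        # aggregate to one row per species (cluster means of predictors)
        xdf = pd.DataFrame(_design_values(table, predictors, log_columns),
                           index=table.index)
        xdf[cluster_col] = table[cluster_col].to_numpy()
        agg = xdf.groupby(cluster_col, sort=True).mean()
        tgt = table.groupby(cluster_col, sort=True)[target_column].first()
        yv = tgt.to_numpy(dtype=float)
        yv_model = (np.log10(np.maximum(yv, 1e-12))
                    if target_column in log_columns else yv)
        miss_sp = np.isnan(yv)
        if (~miss_sp).sum() == 0:
            raise ValueError(f"no observed values for {target_column}")
        X = _design_matrix(agg.to_numpy(dtype=float))
        obs = ~miss_sp
        beta, *_ = np.linalg.lstsq(X[obs], yv_model[obs], rcond=None)
        resid = yv_model[obs] - X[obs] @ beta
        df = max(1, obs.sum() - X.shape[1])
        sse = float(resid @ resid)
        if perturb:
            sigma2_star = sse / rng.chisquare(df)
            XtX = X[obs].T @ X[obs] + 1e-10 * np.eye(X.shape[1])
            cov = sigma2_star * np.linalg.inv(XtX)
            beta_star = _draw_mvn(rng, beta, cov)
        else:
            beta_star = beta
        pred_obs = X[obs] @ beta
        pred_mis = X[miss_sp] @ beta_star
        k = min(donors, int(obs.sum()))
        if k < donors:
            warnings.warn(f"{target_column}: only {k} donors available")
        imputed_sp = yv.copy()
        imputed_sp[miss_sp] = _pmm_match(pred_obs, pred_mis, yv[obs], k, rng)
        per_species = pd.Series(imputed_sp, index=tgt.index)
        return pd.Series(per_species.loc[table[cluster_col]].to_numpy(),
                         index=table.index, name=target_column)

    if level != "observation":
        raise ValueError("level must be 'observation' or 'species'")

    X = _design_matrix(_design_values(table, predictors, log_columns))
    obs = ~miss
    if obs.sum() == 0:
        raise ValueError(f"no observed values for {target_column}")
    fit = fit_random_intercept(y_model[obs], X[obs], codes[obs], len(groups))
    u = fit.blup.copy()
    if perturb:
        sigma2_star = fit.sse / rng.chisquare(fit.df)
        scale = sigma2_star / max(fit.sigma2_e, 1e-12)
        beta_star = _draw_mvn(rng, fit.beta, fit.cov_beta * scale)
        # clusters with no observed rows get a drawn random intercept, so
        # repeated imputations spread over the cluster-effect distribution;
        # the cluster variance itself is redrawn (chi^2) per imputation to
        # propagate its estimation uncertainty from few clusters
        if fit.sigma2_u > 0:
            df_c = max(1, int(fit.observed_groups.sum()) - 1)
            sigma2_u_star = fit.sigma2_u * df_c / rng.chisquare(df_c)
            unseen = ~fit.observed_groups
            u[unseen] = rng.normal(0.0, np.sqrt(sigma2_u_star), unseen.sum())
    else:
        beta_star = fit.beta
    pred_obs = X[obs] @ fit.beta + u[codes[obs]]
    pred_mis = X[miss] @ beta_star + u[codes[miss]]
    k = min(donors, int(obs.sum()))
    if k < donors:
        warnings.warn(f"{target_column}: only {k} donors available")
    out = y_full.copy()
    out[miss] = _pmm_match(pred_obs, pred_mis, y_full[obs], k, rng)
    return pd.Series(out, index=table.index, name=target_column)


@dataclass
class CompletedImputations:
    """m completed copies of the imputation table plus provenance."""

    datasets: list[pd.DataFrame]
    observed_mask: pd.DataFrame  # True where the cell was observed

    @property
    def m(self) -> int:
        return len(self.datasets)


class ChainedPMMImputer(TransformerMixin, BaseEstimator):
    """Chained-equations two-level PMM imputer (sklearn-style).

    Parameters
    ----------
    m : number of completed datasets.
    donors : PMM donor-pool size.
    maxit : chained passes over the incomplete columns.
    seed : base seed; each imputation uses an independent substream.
    perturb : Bayesian coefficient perturbation between imputations.

    ``fit_transform`` returns a :class:`CompletedImputations`; observed
    cells are identical across copies, every imputed cell equals some
    observed donor value of its column.
    """

    def __init__(self, m: int = 100, donors: int = 5, maxit: int = 5,
                 seed: int = 0, perturb: bool = True):
        self.m = m
        self.donors = donors
        self.maxit = maxit
        self.seed = seed
        self.perturb = perturb

    def fit(self, X: pd.DataFrame, y=None):
        missing = [c for c in [ID_COLUMN] + COMPLETE_COLUMNS
                   if c not in X.columns]
        if missing:
            raise ValueError(f"imputation table missing columns {missing}")
        if X[[ID_COLUMN] + COMPLETE_COLUMNS].isna().any().any():
            raise ValueError("id/effort columns must be complete")
        targets = [c for c in SPECIES_LEVEL + OBSERVATION_LEVEL
                   if c in X.columns and X[c].isna().any()]
        # visit order: increasing missingness
        self.visit_order_ = sorted(targets, key=lambda c: X[c].isna().mean())
        self.observed_mask_ = X.notna()
        return self

    def transform(self, X: pd.DataFrame) -> CompletedImputations:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        rngs = spawn_rngs(self.seed, self.m)
        datasets = [self._impute_once(X, rng) for rng in rngs]
        return CompletedImputations(datasets, self.observed_mask_)

    def fit_transform(self, X: pd.DataFrame, y=None) -> CompletedImputations:
        return self.fit(X).transform(X)

    # ------------------------------------------------------------------
    def _impute_once(self, X: pd.DataFrame, rng) -> pd.DataFrame:
        tab = X.copy()
        numeric = [c for c in tab.columns if c not in (ID_COLUMN, "grid_id")]
        # initial fill: random draws from the observed values
        for c in self.visit_order_:
            vals = tab[c].dropna().to_numpy()
            if vals.size == 0:
                raise ValueError(f"column {c} has no observed values")
            n_miss = int(tab[c].isna().sum())
            if c in SPECIES_LEVEL:
                per_sp = tab.groupby(ID_COLUMN)[c].first()
                sp_miss = per_sp.index[per_sp.isna()]
                fill = pd.Series(rng.choice(vals, size=len(sp_miss)),
                                 index=sp_miss)
                merged = per_sp.fillna(fill)
                tab[c] = merged.loc[tab[ID_COLUMN]].to_numpy()
            else:
                tab.loc[tab[c].isna(), c] = rng.choice(vals, size=n_miss)

        mask = {c: X[c].isna().to_numpy() for c in self.visit_order_}
        for _ in range(self.maxit):
            for c in self.visit_order_:
                level = "species" if c in SPECIES_LEVEL else "observation"
                predictors = [p for p in numeric if p != c]
                work = tab.copy()
                work.loc[mask[c], c] = np.nan
                tab[c] = pmm_draw(work, c, predictors, level=level,
                                  donors=self.donors, seed=rng,
                                  perturb=self.perturb)
        return tab


def run_chained_imputation(
    table: pd.DataFrame,
    m: int = 100,
    maxit: int = 5,
    donors: int = 5,
    seed: int = 0,
    perturb: bool = True,
) -> CompletedImputations:
    """Produce ``m`` completed copies of the imputation table."""
    if m < 2:
        raise ValueError("m must be >= 2 for multiple imputation")
    imputer = ChainedPMMImputer(m=m, donors=donors, maxit=maxit, seed=seed,
                                perturb=perturb)
    return imputer.fit_transform(table)
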