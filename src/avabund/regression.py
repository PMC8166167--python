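"""Hierarchical measurement-error regression of density on relative abundance.

The training model links log10 density y (individuals/km^2, from expert
regional abundance over area) to log10 relative abundance x from
checklists, acknowledging that x itself is estimated with error:

    y_i     ~ Normal(b_{s(i)} + m_{s(i)} * x_i_true, sigma)
    x_i_obs ~ Normal(x_i_true, se_i)            (known se_i per record)
    x_i_true ~ Normal(mu_x, tau_x)              (latent-predictor population)
    (b_s, m_s) ~ Normal2(mu, Sigma)             (random slopes/intercepts)

This is a Type-II regression: ignoring the predictor error would attenuate
the slopes.  The posterior is explored by Gibbs sampling with latent
true-x augmentation, conjugate updates for all location parameters and the
residual variance, and a marginal Metropolis step (random effects
integrated out) for the random-effect covariance — the centered conjugate
update suffers the classic small-variance funnel.  Everything is
vectorized across species and observations.  Per-species posterior means
and SDs of (b, m) are the pipeline's downstream currency.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from ._utils import spawn_rngs

ZERO_LOG10_RA = -4.5  # substituted for relative abundance exactly zero


def build_training_table(
    expert_table: pd.DataFrame,
    region_ra: pd.DataFrame,
    zero_value: float = ZERO_LOG10_RA,
    zero_se: float = 0.5,
) -> pd.DataFrame:
    """Join expert regional estimates with regional relative abundance.

    One row per species x region: log10 density from abundance/area, log10
    relative abundance with zeros substituted by ``zero_value`` (and given
    the sentinel SE ``zero_se``).  Rows with nonpositive abundance or area
    are dropped with a warning.
    """
    required = {"species_id", "region_id", "abundance_estimate", "region_area_km2"}
    if not required <= set(expert_table.columns):
        raise ValueError(f"expert table missing {required - set(expert_table.columns)}")
    tab = expert_table.merge(region_ra, on=["species_id", "region_id"], how="left")
    bad = (tab["abundance_estimate"] <= 0) | (tab["region_area_km2"] <= 0)
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} rows with nonpositive "
                      "abundance or area")
        tab = tab[~bad]
    tab = tab.copy()
    tab["rel_abund"] = tab["rel_abund"].fillna(0.0)
    tab["log10_density"] = np.log10(tab["abundance_estimate"]
                                    / tab["region_area_km2"])
    zero = tab["rel_abund"] <= 0
    with np.errstate(divide="ignore"):
        tab["log10_rel_abund"] = np.where(zero, zero_value,
                                          np.log10(tab["rel_abund"]))
    tab["se_log10_rel_abund"] = np.where(
        zero, zero_se, tab.get("se_log10", pd.Series(0.0, index=tab.index)))
    tab["se_log10_rel_abund"] = tab["se_log10_rel_abund"].fillna(zero_se)
    return tab[["species_id", "region_id", "log10_density",
                "log10_rel_abund", "se_log10_rel_abund"]].reset_index(drop=True)


def _chol2(a: np.ndarray, b: np.ndarray, c: np.ndarray):
    """Cholesky factors of stacked 2x2 SPD matrices [[a, b], [b, c]]."""
    l11 = np.sqrt(a)
    l21 = b / l11
    l22 = np.sqrt(np.maximum(c - l21 * l21, 1e-300))
    return l11, l21, l22


def _re_marginal_loglik(phi: np.ndarray, sigma2: float, stats: dict) -> float:
    """Log-likelihood of Sigma(phi) with the random effects integrated out.

    phi = (log sd_b, log sd_m, atanh rho).  Per species, marginally
    y_s ~ N(X_s mu, sigma2 I + X_s Sigma X_s'); Woodbury/Sylvester reduce
    everything to closed-form 2x2 algebra over per-species sufficient
    statistics, vectorized across species.  Terms constant in phi are
    dropped.
    """
    sd_b, sd_m = np.exp(phi[0]), np.exp(phi[1])
    rho = np.tanh(phi[2])
    s11, s12, s22 = sd_b**2, rho * sd_b * sd_m, sd_m**2
    n_s, sx, sxx = stats["n"], stats["sx"], stats["sxx"]
    rb, rm = stats["rb"], stats["rm"]
    # M = I + Sigma A / sigma2 with A = [[n, sx], [sx, sxx]]
    m11 = 1.0 + (s11 * n_s + s12 * sx) / sigma2
    m12 = (s11 * sx + s12 * sxx) / sigma2
    m21 = (s12 * n_s + s22 * sx) / sigma2
    m22 = 1.0 + (s12 * sx + s22 * sxx) / sigma2
    det_m = m11 * m22 - m12 * m21
    if np.any(det_m <= 0):
        return -np.inf
    # B = Sigma^{-1} + A/sigma2 ; quad = (b/sig2)' B^{-1} (b/sig2)
    det_s = s11 * s22 - s12 * s12
    if det_s <= 0:
        return -np.inf
    b11 = s22 / det_s + n_s / sigma2
    b12 = -s12 / det_s + sx / sigma2
    b22 = s11 / det_s + sxx / sigma2
    det_b = b11 * b22 - b12 * b12
    u, v = rb / sigma2, rm / sigma2
    quad = (b22 * u * u - 2.0 * b12 * u * v + b11 * v * v) / det_b
    return float(-0.5 * np.sum(np.log(det_m) - quad))


def _log_prior_phi(phi: np.ndarray, scale: float) -> float:
    """half-t(3) on each random-effect SD, uniform on the correlation."""
    lp = 0.0
    for k in range(2):
        sd = np.exp(phi[k])
        lp += -2.0 * np.log1p(sd * sd / (3.0 * scale * scale)) + phi[k]
    rho = np.tanh(phi[2])
    lp += np.log1p(-rho * rho)  # Jacobian of atanh parametrization
    return float(lp)


def _split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat over (n_chains, n_draws) of one scalar parameter."""
    half = chains.shape[1] // 2
    seqs = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    m, n = seqs.shape
    means = seqs.mean(axis=1)
    b = n * means.var(ddof=1)
    w = seqs.var(axis=1, ddof=1).mean()
    if w <= 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


class MeasurementErrorRegression(RegressorMixin, BaseEstimator):
    """Bayesian random-slope regression with known error in the predictor.

    Parameters
    ----------
    iterations : total Gibbs iterations per chain (including warmup).
    chains : number of independent chains.
    warmup : discarded iterations per chain.
    seed : base seed; chains use spawned substreams.
    prior_tau : SD of the normal prior on the fixed effects.
    prior_re_scale : scale of the half-Student-t(3) priors on the
        random-effect SDs (None: the response SD, the usual weakly
        informative default).  The slope-intercept correlation gets a
        uniform prior.  Sigma is updated by a marginal Metropolis step
        with the random effects integrated out, which avoids the
        small-variance funnel that traps a centered conjugate update.
    sigma_prior_frac : the inverse-gamma prior on the residual variance has
        shape 2 and scale ``sigma_prior_frac * var(y)`` (weakly informative,
        scaling with the response as the usual half-t defaults do).

    Attributes (after fit)
    ----------------------
    coef_table_ : DataFrame with per-species posterior mean b, m and their
        posterior SDs se_b, se_m.
    fixed_intercept_, fixed_slope_, sigma_resid_, Sigma_re_ : population
        parameters (posterior means).
    rhat_ : dict of split-R-hat diagnostics; converged_ : all <= 1.01.
    draws_ : dict of retained posterior draws.
    """

    def __init__(self, iterations: int = 10000, chains: int = 4,
                 warmup: int = 2000, seed: int = 0, prior_tau: float = 5.0,
                 prior_re_scale: float | None = None,
                 sigma_prior_frac: float = 0.25, mh_steps: int = 3,
                 mh_step_size: float = 0.25):
        self.iterations = iterations
        self.chains = chains
        self.warmup = warmup
        self.seed = seed
        self.prior_tau = prior_tau
        self.prior_re_scale = prior_re_scale
        self.sigma_prior_frac = sigma_prior_frac
        self.mh_steps = mh_steps
        self.mh_step_size = mh_step_size

    # ------------------------------------------------------------------
    def fit(self, X, y, groups=None, x_se=None):
        x_obs = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if groups is None:
            raise ValueError("groups (species labels) are required")
        if x_obs.size != y.size or len(groups) != y.size:
            raise ValueError("X, y and groups must have equal length")
        if not (np.isfinite(x_obs).all() and np.isfinite(y).all()):
            raise ValueError("non-finite values in X or y")
        se = (np.zeros_like(x_obs) if x_se is None
              else np.asarray(x_se, dtype=float).reshape(-1))
        if np.any(se < 0):
            raise ValueError("x_se must be nonnegative")

        species, codes = np.unique(np.asarray(groups), return_inverse=True)
        n_sp = species.size
        if n_sp < 2:
            raise ValueError("need at least 2 species")
        n = y.size

        keep = self.iterations - self.warmup
        if keep < 2:
            raise ValueError("iterations must exceed warmup by at least 2")

        rngs = spawn_rngs(self.seed, self.chains)
        draws_b = np.empty((self.chains, keep, n_sp))
        draws_m = np.empty((self.chains, keep, n_sp))
        draws_mu = np.empty((self.chains, keep, 2))
        draws_sigma = np.empty((self.chains, keep))
        draws_Sigma = np.empty((self.chains, keep, 3))  # var_b, cov, var_m

        var_y = max(y.var(), 1e-6)
        a0, b0 = 2.0, self.sigma_prior_frac * var_y
        re_scale = (self.prior_re_scale if self.prior_re_scale is not None
                    else max(np.sqrt(var_y), 1e-3))
        tau2 = self.prior_tau ** 2
        se2 = se ** 2
        exact_x = se2 == 0

        for c, rng in enumerate(rngs):
            # initial values: pooled OLS + small jitter
            Xd = np.column_stack([np.ones(n), x_obs])
            beta0, *_ = np.linalg.lstsq(Xd, y, rcond=None)
            mu = beta0 + 0.1 * rng.standard_normal(2)
            theta = np.tile(mu, (n_sp, 1)) + 0.05 * rng.standard_normal((n_sp, 2))
            Sigma = np.diag([0.1, 0.05])
            sigma2 = var_y
            x_true = x_obs.copy()
            mu_x = float(x_obs.mean())
            tau2_x = max(float(x_obs.var()), 1e-4)
            var_x = max(float(x_obs.var()), 1e-6)

            for it in range(self.iterations):
                b_i = theta[codes, 0]
                m_i = theta[codes, 1]
                # latent true predictor (population prior N(mu_x, tau2_x))
                se2_safe = np.where(exact_x, 1.0, se2)
                prec_post = (np.where(exact_x, np.inf, 1.0 / se2_safe)
                             + 1.0 / tau2_x + m_i ** 2 / sigma2)
                mean_post = np.where(
                    exact_x, x_obs,
                    (np.where(exact_x, 0.0, x_obs / se2_safe) + mu_x / tau2_x
                     + m_i * (y - b_i) / sigma2) / prec_post)
                sd_post = np.where(exact_x, 0.0, 1.0 / np.sqrt(prec_post))
                x_true = mean_post + sd_post * rng.standard_normal(n)

                # hyperparameters of the latent-predictor population
                prec_mux = n / tau2_x + 1.0 / tau2
                mu_x = (x_true.sum() / tau2_x) / prec_mux \
                    + rng.standard_normal() / np.sqrt(prec_mux)
                ssx = float(((x_true - mu_x) ** 2).sum())
                tau2_x = 1.0 / rng.gamma(2.0 + n / 2.0,
                                         1.0 / (0.5 * var_x + 0.5 * ssx))

                # sufficient statistics per species
                n_s = np.bincount(codes, minlength=n_sp).astype(float)
                sx = np.bincount(codes, weights=x_true, minlength=n_sp)
                sxx = np.bincount(codes, weights=x_true ** 2, minlength=n_sp)
                sy = np.bincount(codes, weights=y, minlength=n_sp)
                sxy = np.bincount(codes, weights=x_true * y, minlength=n_sp)

                # random-effect covariance: marginal Metropolis on
                # (log sd_b, log sd_m, atanh rho), theta integrated out
                stats = {
                    "n": n_s, "sx": sx, "sxx": sxx,
                    "rb": sy - mu[0] * n_s - mu[1] * sx,
                    "rm": sxy - mu[0] * sx - mu[1] * sxx,
                }
                sd_b = max(np.sqrt(Sigma[0, 0]), 1e-8)
                sd_m = max(np.sqrt(Sigma[1, 1]), 1e-8)
                rho_re = np.clip(Sigma[0, 1] / (sd_b * sd_m), -0.999, 0.999)
                phi = np.array([np.log(sd_b), np.log(sd_m), np.arctanh(rho_re)])
                lp = (_re_marginal_loglik(phi, sigma2, stats)
                      + _log_prior_phi(phi, re_scale))
                for _ in range(self.mh_steps):
                    cand = phi + self.mh_step_size * rng.standard_normal(3)
                    lp_cand = (_re_marginal_loglik(cand, sigma2, stats)
                               + _log_prior_phi(cand, re_scale))
                    if np.log(rng.random()) < lp_cand - lp:
                        phi, lp = cand, lp_cand
                sd_b, sd_m = np.exp(phi[0]), np.exp(phi[1])
                rho_re = np.tanh(phi[2])
                Sigma = np.array([
                    [sd_b**2, rho_re * sd_b * sd_m],
                    [rho_re * sd_b * sd_m, sd_m**2]])

                # per-species (b, m): conjugate bivariate normal
                Sinv = np.linalg.inv(Sigma)
                A = Sinv[0, 0] + n_s / sigma2
                B = Sinv[0, 1] + sx / sigma2
                C = Sinv[1, 1] + sxx / sigma2
                r1 = Sinv @ mu
                rhs1 = r1[0] + sy / sigma2
                rhs2 = r1[1] + sxy / sigma2
                det = A * C - B * B
                mb = (C * rhs1 - B * rhs2) / det
                mm = (A * rhs2 - B * rhs1) / det
                # covariance = inv(precision); cholesky, then sample
                ca, cb, cc = C / det, -B / det, A / det
                l11, l21, l22 = _chol2(ca, cb, cc)
                z1 = rng.standard_normal(n_sp)
                z2 = rng.standard_normal(n_sp)
                theta = np.column_stack([mb + l11 * z1, mm + l21 * z1 + l22 * z2])

                # fixed effects
                prec_mu = n_sp * Sinv + np.eye(2) / tau2
                cov_mu = np.linalg.inv(prec_mu)
                mean_mu = cov_mu @ (Sinv @ theta.sum(axis=0))
                mu = rng.multivariate_normal(mean_mu, cov_mu)

                # residual variance
                resid = y - theta[codes, 0] - theta[codes, 1] * x_true
                sigma2 = 1.0 / rng.gamma(a0 + n / 2.0,
                                         1.0 / (b0 + 0.5 * resid @ resid))

                if it >= self.warmup:
                    k = it - self.warmup
                    draws_b[c, k] = theta[:, 0]
                    draws_m[c, k] = theta[:, 1]
                    draws_mu[c, k] = mu
                    draws_sigma[c, k] = np.sqrt(sigma2)
                    draws_Sigma[c, k] = (Sigma[0, 0], Sigma[0, 1], Sigma[1, 1])

        self.species_ = species
        self.draws_ = {
            "b": draws_b.reshape(-1, n_sp), "m": draws_m.reshape(-1, n_sp),
            "mu": draws_mu.reshape(-1, 2), "sigma": draws_sigma.reshape(-1),
            "Sigma": draws_Sigma.reshape(-1, 3),
        }
        self.coef_table_ = pd.DataFrame({
            "species_id": species,
            "b": self.draws_["b"].mean(axis=0),
            "m": self.draws_["m"].mean(axis=0),
            "se_b": self.draws_["b"].std(axis=0, ddof=1),
            "se_m": self.draws_["m"].std(axis=0, ddof=1),
        })
        self.fixed_intercept_ = float(self.draws_["mu"][:, 0].mean())
        self.fixed_slope_ = float(self.draws_["mu"][:, 1].mean())
        self.sigma_resid_ = float(self.draws_["sigma"].mean())
        sm = self.draws_["Sigma"].mean(axis=0)
        self.Sigma_re_ = np.array([[sm[0], sm[1]], [sm[1], sm[2]]])
        self.rhat_ = {
            "fixed_intercept": _split_rhat(draws_mu[:, :, 0]),
            "fixed_slope": _split_rhat(draws_mu[:, :, 1]),
            "sigma": _split_rhat(draws_sigma),
        }
        self.converged_ = all(r <= 1.01 for r in self.rhat_.values())
        if not self.converged_:
            warnings.warn(f"possible non-convergence, split-Rhat = {self.rhat_}")
        self.n_features_in_ = 1
        return self

    # ------------------------------------------------------------------
    def predict(self, X, groups=None):
        """Posterior-mean prediction of log10 density at log10 RA ``X``."""
        x = np.asarray(X, dtype=float).reshape(-1)
        if groups is None:
            return self.fixed_intercept_ + self.fixed_slope_ * x
        coef = self.coef_table_.set_index("species_id")
        b = np.array([coef["b"].get(g, self.fixed_intercept_) for g in groups])
        m = np.array([coef["m"].get(g, self.fixed_slope_) for g in groups])
        return b + m * x

    def coefficient_quantiles(self, q) -> dict[str, pd.DataFrame]:
        """Posterior quantiles of per-species b and m (rows = species)."""
        out = {}
        for key in ("b", "m"):
            qs = np.quantile(self.draws_[key], q, axis=0).T
            out[key] = pd.DataFrame(qs, index=self.species_,
                                    columns=[f"q{qq}" for qq in np.atleast_1d(q)])
        return out


def fit_measurement_error_model(
    records: pd.DataFrame,
    iterations: int = 10000,
    chains: int = 4,
    warmup: int = 2000,
    seed: int = 0,
    **kwargs,
) -> MeasurementErrorRegression:
    """Fit the hierarchical model from a training-record table."""
    if records["species_id"].nunique() < 2:
        raise ValueError("need at least 2 species")
    model = MeasurementErrorRegression(iterations=iterations, chains=chains,
                                       warmup=warmup, seed=seed, **kwargs)
    model.fit(records["log10_rel_abund"].to_numpy(),
              records["log10_density"].to_numpy(),
              groups=records["species_id"].to_numpy(),
              x_se=records["se_log10_rel_abund"].to_numpy())
    return model


def predict_log_density(
    coef: pd.DataFrame | pd.Series,
    x,
    rho: float = -1.0,
    sigma_resid: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SE of predicted log10 density at log10 RA ``x``.

    The SE propagates the coefficient SEs assuming correlation ``rho``
    between intercept and slope errors (default -1: an overestimated
    intercept implies a shallower slope):

        se^2 = se_b^2 + x^2 se_m^2 + 2 x rho se_b se_m

    which collapses to |se_b - x * se_m| at rho = -1.  Residual noise is
    excluded unless ``sigma_resid`` is given (then added in quadrature).
    """
    x = np.asarray(x, dtype=float)
    b, m = np.asarray(coef["b"], dtype=float), np.asarray(coef["m"], dtype=float)
    se_b = np.asarray(coef["se_b"], dtype=float)
    se_m = np.asarray(coef["se_m"], dtype=float)
    mean = b + m * x
    var = se_b ** 2 + x ** 2 * se_m ** 2 + 2.0 * x * rho * se_b * se_m
    se = np.sqrt(np.maximum(var, 0.0))
    if sigma_resid is not None:
        se = np.sqrt(se ** 2 + sigma_resid ** 2)
    return mean, se


def bayes_r2(model: MeasurementErrorRegression, records: pd.DataFrame) -> float:
    """Posterior-mean Bayesian R^2: var(pred) / (var(pred) + sigma^2)."""
    x = records["log10_rel_abund"].to_numpy()
    codes = pd.Categorical(records["species_id"],
                           categories=model.species_).codes
    if (codes < 0).any():
        raise ValueError("records contain species not in the fit")
    b = model.draws_["b"][:, codes]
    m = model.draws_["m"][:, codes]
    pred = b + m * x[None, :]
    var_pred = pred.var(axis=1)
    sig2 = model.draws_["sigma"] ** 2
    denom = var_pred + sig2
    r2 = np.where(denom > 0, var_pred / denom, 0.0)
    return float(r2.mean())
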