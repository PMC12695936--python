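"""Bayesian Tobit moderated regression by Gibbs sampling.

Censored cells of y, x, and z are augmented with latent true scores each
sweep: censored y* from a truncated normal about its regression mean;
censored x* from the conjugate normal combining its marginal prior
N(mu_x, var_x) with the outcome likelihood (linear in x* with slope
b1 + b3 z*), truncated to the censored region — symmetrically for z*.  The
interaction column is rebuilt from the current x*, z* at every sweep, so
ceiling/floor effects propagate into the product term.  Regression
coefficients then get a conjugate multivariate-normal update, variances
precision-gamma updates, exogenous means normal updates.

By default x* and z* carry independent marginal normals (their correlation
enters only indirectly through the regression term in censored-cell
conditionals); ``bivariate_exo=True`` instead models (x*, z*) jointly with
an inverse-Wishart prior on their covariance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from .censoring import CEILING, FLOOR, ModRegData
from .conventional import TERMS
from .mcmc import (
    PosteriorChains,
    PriorSpec,
    percentile_interval,
    sample_truncated_normal,
)

__all__ = ["gibbs_modreg_tobit", "TobitModRegBayesResults"]

PARAMS = ("beta0", "beta1", "beta2", "beta3", "sigma_e2",
          "mu_x", "mu_z", "var_x", "var_z")


def _trunc_limits(var):
    lo = np.where(var.status == CEILING, var.bounds.ceiling, -np.inf)
    hi = np.where(var.status == FLOOR, var.bounds.floor, np.inf)
    return lo, hi


def gibbs_modreg_tobit(
    data: ModRegData,
    priors: PriorSpec = PriorSpec(),
    n_chains: int = 2,
    burn_in: int = 1_000,
    n_iter: int = 5_000,
    seed: int | None = None,
    bivariate_exo: bool = False,
    fix_beta: np.ndarray | None = None,
    keep_augmented: bool = False,
) -> PosteriorChains:
    """Run the augmented Gibbs sampler; deterministic given ``seed``.

    ``fix_beta`` holds the regression coefficients at given values (used by
    marginal-distribution diagnostics).  ``keep_augmented`` stores the final
    sweep's augmented scores and design matrix in ``chains.diagnostics``.
    The defaults are desk-scale; the reference analysis configuration is
    2 chains with 30,000 burn-in and 100,000 kept iterations.
    """
    if n_chains < 2:
        raise ValueError("need at least 2 chains for the PSRF diagnostic")
    if burn_in <= 0 or n_iter <= 0:
        raise ValueError("iteration counts must be positive")
    for name in ("y", "x", "z"):
        if not getattr(data, name).is_interior.any():
            raise ValueError(f"variable {name} has no interior observations")

    seeds = np.random.SeedSequence(seed).spawn(n_chains)
    draws = {name: np.empty((n_chains, n_iter)) for name in PARAMS}
    diagnostics: dict = {}
    for chain in range(n_chains):
        rng = np.random.default_rng(seeds[chain])
        overdisperse = 0.0 if chain == 0 else (1.0 if chain % 2 else -1.0)
        diag = _run_chain(
            data, priors, n_iter, burn_in, rng,
            {name: draws[name][chain] for name in PARAMS},
            overdisperse, bivariate_exo, fix_beta, keep_augmented,
        )
        if keep_augmented:
            diagnostics[f"chain{chain}"] = diag
    return PosteriorChains(draws=draws, burn_in=burn_in, seed=seed,
                           diagnostics=diagnostics)


def _run_chain(data, priors, n_iter, burn_in, rng, out, overdisperse,
               bivariate_exo, fix_beta, keep_augmented):
    n = data.n
    ys = data.y.values.copy()
    xs = data.x.values.copy()
    zs = data.z.values.copy()
    cy = data.y.status != 0
    cx = data.x.status != 0
    cz = data.z.status != 0
    ylo, yhi = _trunc_limits(data.y)
    xlo, xhi = _trunc_limits(data.x)
    zlo, zhi = _trunc_limits(data.z)

    # starts: OLS on observed scores, observed moments for the exogenous part
    W = np.column_stack([np.ones(n), xs, zs, xs * zs])
    beta, *_ = np.linalg.lstsq(W, ys, rcond=None)
    sig_e2 = max(float(np.var(ys - W @ beta)), 1e-3)
    mu_x, mu_z = float(np.mean(xs)), float(np.mean(zs))
    var_x = max(float(np.var(xs)), 1e-3)
    var_z = max(float(np.var(zs)), 1e-3)
    cov_xz = float(np.cov(xs, zs, ddof=0)[0, 1])
    if overdisperse:
        beta = beta + overdisperse * 2.0 * np.sqrt(sig_e2 / n)
        sig_e2 *= np.exp(overdisperse)
        var_x *= np.exp(overdisperse)
        var_z *= np.exp(overdisperse)
        mu_x += overdisperse * 2.0 * np.sqrt(var_x / n)
        mu_z += overdisperse * 2.0 * np.sqrt(var_z / n)
    if fix_beta is not None:
        beta = np.asarray(fix_beta, dtype=float)

    v0 = priors.mean_prior_variance
    a0 = priors.variance_prior_shape
    b0 = priors.variance_prior_rate
    prior_prec_beta = np.eye(4) / v0
    # diffuse inverse-Wishart for the joint exogenous covariance option
    iw_df0, iw_scale0 = 3.0, np.eye(2) * 1e-3

    for it in range(burn_in + n_iter):
        se = np.sqrt(sig_e2)
        # censored outcome scores
        if cy.any():
            m = (beta[0] + beta[1] * xs + beta[2] * zs
                 + beta[3] * xs * zs)[cy]
            ys[cy] = sample_truncated_normal(rng, m, se, ylo[cy], yhi[cy])
        # censored focal-predictor scores: marginal prior x outcome term
        if cx.any():
            if bivariate_exo:
                pm = mu_x + (cov_xz / var_z) * (zs[cx] - mu_z)
                pv = var_x - cov_xz**2 / var_z
            else:
                pm, pv = mu_x, var_x
            slope = beta[1] + beta[3] * zs[cx]
            prec = 1.0 / pv + slope**2 / sig_e2
            mean = (pm / pv + slope * (ys[cx] - beta[0] - beta[2] * zs[cx])
                    / sig_e2) / prec
            xs[cx] = sample_truncated_normal(
                rng, mean, 1.0 / np.sqrt(prec), xlo[cx], xhi[cx]
            )
        # censored moderator scores, symmetric
        if cz.any():
            if bivariate_exo:
                pm = mu_z + (cov_xz / var_x) * (xs[cz] - mu_x)
                pv = var_z - cov_xz**2 / var_x
            else:
                pm, pv = mu_z, var_z
            slope = beta[2] + beta[3] * xs[cz]
            prec = 1.0 / pv + slope**2 / sig_e2
            mean = (pm / pv + slope * (ys[cz] - beta[0] - beta[1] * xs[cz])
                    / sig_e2) / prec
            zs[cz] = sample_truncated_normal(
                rng, mean, 1.0 / np.sqrt(prec), zlo[cz], zhi[cz]
            )
        # design matrix rebuilt from current true scores each sweep
        W = np.column_stack([np.ones(n), xs, zs, xs * zs])
        if fix_beta is None:
            prec_b = W.T @ W / sig_e2 + prior_prec_beta
            L = np.linalg.cholesky(prec_b)
            mean_b = np.linalg.solve(prec_b, W.T @ ys / sig_e2)
            beta = mean_b + np.linalg.solve(L.T, rng.standard_normal(4))
        resid = ys - W @ beta
        sig_e2 = 1.0 / rng.gamma(a0 + 0.5 * n,
                                 1.0 / (b0 + 0.5 * resid @ resid))
        # exogenous distribution
        if bivariate_exo:
            d = np.column_stack([xs - mu_x, zs - mu_z])
            sigma = invwishart.rvs(df=iw_df0 + n, scale=iw_scale0 + d.T @ d,
                                   random_state=rng)
            var_x, var_z = sigma[0, 0], sigma[1, 1]
            cov_xz = sigma[0, 1]
            prec_m = n * np.linalg.inv(sigma) + np.eye(2) / v0
            mean_m = np.linalg.solve(
                prec_m, n * np.linalg.inv(sigma) @ [np.mean(xs), np.mean(zs)]
            )
            Lm = np.linalg.cholesky(prec_m)
            mu_x, mu_z = mean_m + np.linalg.solve(
                Lm.T, rng.standard_normal(2)
            )
        else:
            prec = n / var_x + 1.0 / v0
            mu_x = rng.normal(xs.sum() / var_x / prec, 1.0 / np.sqrt(prec))
            var_x = 1.0 / rng.gamma(
                a0 + 0.5 * n, 1.0 / (b0 + 0.5 * np.sum((xs - mu_x) ** 2))
            )
            prec = n / var_z + 1.0 / v0
            mu_z = rng.normal(zs.sum() / var_z / prec, 1.0 / np.sqrt(prec))
            var_z = 1.0 / rng.gamma(
                a0 + 0.5 * n, 1.0 / (b0 + 0.5 * np.sum((zs - mu_z) ** 2))
            )

        if it >= burn_in:
            j = it - burn_in
            out["beta0"][j], out["beta1"][j] = beta[0], beta[1]
            out["beta2"][j], out["beta3"][j] = beta[2], beta[3]
            out["sigma_e2"][j] = sig_e2
            out["mu_x"][j], out["mu_z"][j] = mu_x, mu_z
            out["var_x"][j], out["var_z"][j] = var_x, var_z

    if keep_augmented:
        return {"x_star": xs.copy(), "z_star": zs.copy(), "y_star": ys.copy(),
                "design": W.copy()}
    return None


class TobitModRegBayesResults:
    """Posterior summaries for Bayesian Tobit moderated regression."""

    def __init__(self, model, chains: PosteriorChains):
        self.model = model
        self.chains = chains

    @property
    def converged(self) -> bool:
        return self.chains.converged

    @property
    def params(self) -> np.ndarray:
        """Posterior means of the regression coefficients."""
        return np.array([self.chains.pooled(f"beta{i}").mean()
                         for i in range(4)])

    def beta_interval(self, index: int, cred: float = 0.95):
        return percentile_interval(self.chains.pooled(f"beta{index}"), cred)

    def summary(self, cred: float = 0.95) -> pd.DataFrame:
        table = self.chains.summary(cred)
        table.index = list(TERMS) + list(table.index[4:])
        return table
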