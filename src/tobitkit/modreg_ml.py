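"""Maximum-likelihood Tobit moderated regression.

Model: latent true scores follow

    y* = b0 + b1 x* + b2 z* + b3 x* z* + e,   e ~ N(0, sigma_e^2),

with (x*, z*) bivariate normal (exogenous means/covariance estimated) and
each observed variable clipped at its own floor/ceiling.  When only the
outcome is censored this is the classical Tobit regression likelihood:
normal density for interior y, normal tail probability at a bound.  When a
predictor or the moderator is censored, its dimension is integrated out of
the joint likelihood over the censored region; the integrals are evaluated
by Gauss-Legendre quadrature on the censored interval truncated where the
conditional-normal integrand reaches numerical zero (the integrand stays
analytic, so the rule converges exponentially in the node count), with a
tensor-product rule when both exogenous variables are censored.  The five
computational branches (all-interior, y-only, one exogenous, one exogenous
plus y, both exogenous) cover all 27 floor/interior/ceiling patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import log_ndtr, logsumexp
from scipy.stats import norm
from statsmodels.tools.numdiff import approx_hess

from .censoring import CEILING, FLOOR, INTERIOR, ModRegData
from .conventional import TERMS, simple_slope

__all__ = [
    "ModRegParams",
    "TobitModeratedRegression",
    "TobitModRegMLResults",
    "modreg_censored_loglik",
    "tobit_regression_outcome_only",
    "fit_modreg_tobit_ml",
    "wald_inference",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class ModRegParams:
    """Regression coefficients, residual variance, and the exogenous
    true-score distribution (mean vector and covariance of x*, z*)."""

    beta: np.ndarray
    sigma_e2: float
    mu_x: float = 0.0
    mu_z: float = 0.0
    var_x: float = 1.0
    var_z: float = 1.0
    cov_xz: float = 0.0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (4,):
            raise ValueError("beta must have 4 entries")
        if self.sigma_e2 <= 0:
            raise ValueError("sigma_e2 must be positive")
        if self.var_x <= 0 or self.var_z <= 0 or self.exo_det <= 0:
            raise ValueError("exogenous covariance is not positive definite")

    @property
    def exo_det(self) -> float:
        return self.var_x * self.var_z - self.cov_xz**2

    @property
    def exo_corr(self) -> float:
        return self.cov_xz / np.sqrt(self.var_x * self.var_z)

    def as_array(self) -> np.ndarray:
        return np.concatenate(
            [self.beta,
             [self.sigma_e2, self.mu_x, self.mu_z, self.var_x, self.var_z,
              self.cov_xz]]
        )


PARAM_NAMES = list(TERMS) + ["sigma_e2", "mu_x", "mu_z", "var_x", "var_z",
                             "cov_xz"]


def _ylik(y, status, m, sig_e, floor_y, ceil_y):
    """Outcome log-likelihood term: log density for interior y, log tail
    probability at a bound.  Broadcasts y/status against the mean array m."""
    y = np.asarray(y, float)
    status = np.asarray(status)
    y, status, m = np.broadcast_arrays(y, status, m)
    out = np.empty(m.shape)
    mask = status == INTERIOR
    if mask.any():
        r = (y[mask] - m[mask]) / sig_e
        out[mask] = -0.5 * r * r - np.log(sig_e) - 0.5 * _LOG2PI
    mask = status == CEILING
    if mask.any():
        out[mask] = log_ndtr((m[mask] - ceil_y) / sig_e)
    mask = status == FLOOR
    if mask.any():
        out[mask] = log_ndtr((floor_y - m[mask]) / sig_e)
    return out


_TAIL = 8.5  # integration reach in conditional SDs; Gaussian mass beyond
# this is ~1e-17, far below the optimizer's resolution


def _region(status, bounds, mean, sd):
    """Finite integration limits (lo, hi) covering the censored region of
    one variable.  A ceiling region [b, inf) is truncated at
    max(b, mean) + _TAIL * sd, where the conditional-normal integrand has
    decayed to numerical zero; floors symmetrically.  Keeping the
    integration in the original coordinate preserves the integrand's
    analyticity, so Gauss-Legendre converges exponentially in the node
    count."""
    at_ceiling = status == CEILING
    lo = np.where(at_ceiling, bounds.ceiling,
                  np.minimum(bounds.floor, mean) - _TAIL * sd)
    hi = np.where(at_ceiling, np.maximum(bounds.ceiling, mean) + _TAIL * sd,
                  bounds.floor)
    return lo, hi


class TobitModeratedRegression:
    """Tobit moderated regression model (ML or Bayesian estimation).

    The ML fit automatically uses the closed-form outcome-only likelihood
    when x and z are fully observed and the marginal quadrature likelihood
    otherwise; ``fit(full=True)`` forces the general path.
    """

    def __init__(
        self,
        data: ModRegData,
        quadrature_nodes: int = 40,
        estimate_exo_correlation: bool = True,
        measurement_inflation: float = 0.0,
    ):
        self.data = data
        self.nodes = int(quadrature_nodes)
        self.estimate_exo_correlation = estimate_exo_correlation
        # optional additive error variance reproducing the small-variance
        # single-indicator identification device; 0 = exact formulation
        self.inflation = float(measurement_inflation)
        self._gl_t, self._gl_w = np.polynomial.legendre.leggauss(self.nodes)
        xs, zs = data.x.status, data.z.status
        self._m_int = (xs == INTERIOR) & (zs == INTERIOR)
        self._m_xc = (xs != INTERIOR) & (zs == INTERIOR)
        self._m_zc = (xs == INTERIOR) & (zs != INTERIOR)
        self._m_xzc = (xs != INTERIOR) & (zs != INTERIOR)
        self.exogenous_observed = (
            data.x.bounds.unbounded and data.z.bounds.unbounded
        )

    # -- likelihood -------------------------------------------------------
    def loglike(self, params: ModRegParams, nodes: int | None = None) -> float:
        """Marginal log-likelihood of the observed (y, x, z) sample."""
        if nodes is not None and nodes != self.nodes:
            t, w = np.polynomial.legendre.leggauss(int(nodes))
        else:
            t, w = self._gl_t, self._gl_w
        d = self.data
        b0, b1, b2, b3 = params.beta
        sig_e = np.sqrt(params.sigma_e2 + self.inflation)
        mu_x, mu_z = params.mu_x, params.mu_z
        vx = params.var_x + self.inflation
        vz = params.var_z + self.inflation
        cxz = params.cov_xz
        if vx * vz - cxz * cxz <= 0:
            raise ValueError("exogenous covariance is not positive definite")
        aY, bY = d.y.bounds.floor, d.y.bounds.ceiling
        logw = np.log(w / 2.0)

        def mean_y(x, z):
            return b0 + b1 * x + b2 * z + b3 * x * z

        ll = 0.0
        # (i)/(ii): x and z interior -- bivariate exogenous density plus the
        # outcome density or tail probability
        m = self._m_int
        if m.any():
            x, z = d.x.values[m], d.z.values[m]
            dx, dz = x - mu_x, z - mu_z
            det = vx * vz - cxz * cxz
            quad = (vz * dx * dx - 2 * cxz * dx * dz + vx * dz * dz) / det
            ll += float(np.sum(-0.5 * (quad + np.log(det)) - _LOG2PI))
            ll += float(np.sum(
                _ylik(d.y.values[m], d.y.status[m], mean_y(x, z), sig_e, aY, bY)
            ))

        # (iii)/(iv): one exogenous variable censored -- 1-D quadrature over
        # its censored region, conditional on the interior one
        for mask, cens, other, slope_pair in (
            (self._m_xc, d.x, d.z, "x"),
            (self._m_zc, d.z, d.x, "z"),
        ):
            if not mask.any():
                continue
            o = other.values[mask]
            if slope_pair == "x":
                mu_c, v_c, mu_o, v_o = mu_x, vx, mu_z, vz
            else:
                mu_c, v_c, mu_o, v_o = mu_z, vz, mu_x, vx
            ll += float(np.sum(norm.logpdf(o, loc=mu_o, scale=np.sqrt(v_o))))
            c_mean = mu_c + (cxz / v_o) * (o - mu_o)
            c_sd = float(np.sqrt(v_c - cxz * cxz / v_o))
            lo, hi = _region(cens.status[mask], cens.bounds, c_mean, c_sd)
            half = (hi - lo) / 2.0  # (R,)
            g = lo[:, None] + half[:, None] * (t[None, :] + 1.0)  # (R, Q)
            ldens = (-0.5 * ((g - c_mean[:, None]) / c_sd) ** 2
                     - np.log(c_sd) - 0.5 * _LOG2PI)
            if slope_pair == "x":
                my = mean_y(g, o[:, None])
            else:
                my = mean_y(o[:, None], g)
            lg = _ylik(d.y.values[mask][:, None], d.y.status[mask][:, None],
                       my, sig_e, aY, bY) + ldens
            ll += float(np.sum(
                logsumexp(lg + logw[None, :] + np.log(2.0 * half)[:, None],
                          axis=1)
            ))

        # (v): both exogenous variables censored -- tensor-product rule over
        # the rectangle, z conditional on the x node
        m = self._m_xzc
        if m.any():
            sx = float(np.sqrt(vx))
            R = int(m.sum())
            lo, hi = _region(d.x.status[m], d.x.bounds,
                             np.full(R, mu_x), sx)
            half_x = (hi - lo) / 2.0
            xg = lo[:, None] + half_x[:, None] * (t[None, :] + 1.0)  # (R, Q)
            ldens_x = (-0.5 * ((xg - mu_x) / sx) ** 2 - np.log(sx)
                       - 0.5 * _LOG2PI)
            zc_mean = mu_z + (cxz / vx) * (xg - mu_x)  # (R, Q)
            zc_sd = float(np.sqrt(vz - cxz * cxz / vx))
            va, vb = _region(d.z.status[m][:, None], d.z.bounds, zc_mean,
                             zc_sd)
            half_z = (vb - va) / 2.0
            zg = va[..., None] + half_z[..., None] * (t[None, None, :] + 1.0)
            ldens_z = (-0.5 * ((zg - zc_mean[..., None]) / zc_sd) ** 2
                       - np.log(zc_sd) - 0.5 * _LOG2PI)  # (R, Q, Q)
            my = mean_y(xg[..., None], zg)
            lg = (_ylik(d.y.values[m][:, None, None],
                        d.y.status[m][:, None, None], my, sig_e, aY, bY)
                  + ldens_x[..., None] + ldens_z)
            lw = (lg + logw[None, :, None] + np.log(2.0 * half_x)[:, None, None]
                  + logw[None, None, :] + np.log(2.0 * half_z)[..., None])
            ll += float(np.sum(logsumexp(lw, axis=(1, 2))))
        return ll

    def loglike_outcome_only(self, beta, sigma_e2) -> float:
        """Classical Tobit likelihood for censoring confined to the outcome
        (x, z fully observed and conditioned on)."""
        d = self.data
        x, z = d.x.values, d.z.values
        m = beta[0] + beta[1] * x + beta[2] * z + beta[3] * x * z
        sig_e = np.sqrt(sigma_e2 + self.inflation)
        return float(np.sum(
            _ylik(d.y.values, d.y.status, m, sig_e,
                  d.y.bounds.floor, d.y.bounds.ceiling)
        ))

    # -- ML fit -----------------------------------------------------------
    def start_params(self) -> ModRegParams:
        """OLS on observed scores for beta; observed moments for the
        exogenous distribution."""
        d = self.data
        x, z = d.x.values, d.z.values
        W = np.column_stack([np.ones(d.n), x, z, x * z])
        beta, *_ = np.linalg.lstsq(W, d.y.values, rcond=None)
        resid = d.y.values - W @ beta
        r = float(np.clip(np.corrcoef(x, z)[0, 1], -0.9, 0.9))
        vx = max(float(np.var(x)), 1e-4)
        vz = max(float(np.var(z)), 1e-4)
        return ModRegParams(
            beta=beta,
            sigma_e2=max(float(np.var(resid)), 1e-4),
            mu_x=float(np.mean(x)),
            mu_z=float(np.mean(z)),
            var_x=vx,
            var_z=vz,
            cov_xz=r * np.sqrt(vx * vz),
        )

    def _pack(self, p: ModRegParams) -> np.ndarray:
        theta = list(p.beta) + [np.log(p.sigma_e2)]
        if not self.exogenous_observed:
            theta += [p.mu_x, p.mu_z, np.log(p.var_x), np.log(p.var_z)]
            if self.estimate_exo_correlation:
                theta.append(np.arctanh(np.clip(p.exo_corr, -0.99, 0.99)))
        return np.array(theta)

    def _unpack(self, theta: np.ndarray) -> ModRegParams:
        beta = theta[:4]
        sigma_e2 = np.exp(theta[4])
        if self.exogenous_observed:
            d = self.data
            return ModRegParams(
                beta, sigma_e2,
                mu_x=float(np.mean(d.x.values)), mu_z=float(np.mean(d.z.values)),
                var_x=max(float(np.var(d.x.values)), 1e-8),
                var_z=max(float(np.var(d.z.values)), 1e-8),
            )
        mu_x, mu_z = theta[5], theta[6]
        vx, vz = np.exp(theta[7]), np.exp(theta[8])
        if self.estimate_exo_correlation:
            r = np.tanh(theta[9])
        else:
            r = 0.0
        return ModRegParams(beta, sigma_e2, mu_x, mu_z, vx, vz,
                            r * np.sqrt(vx * vz))

    def fit(self, start: ModRegParams | None = None, full: bool = False,
            gtol: float = 1e-6, maxiter: int = 1000) -> "TobitModRegMLResults":
        for name in ("y", "x", "z"):
            if not getattr(self.data, name).is_interior.any():
                raise ValueError(
                    f"variable {name} has no interior observations"
                )
        start = start or self.start_params()
        outcome_only = self.exogenous_observed and not full

        if outcome_only:
            def nll(theta):
                try:
                    return -self.loglike_outcome_only(theta[:4],
                                                      np.exp(theta[4]))
                except (ValueError, FloatingPointError):
                    return 1e12
        else:
            def nll(theta):
                try:
                    return -self.loglike(self._unpack(theta))
                except (ValueError, FloatingPointError):
                    return 1e12

        theta0 = self._pack(start)[: 5 if outcome_only else None]
        res = minimize(nll, theta0, method="BFGS",
                       options={"gtol": gtol, "maxiter": maxiter})
        # accept "precision loss" exits whose gradient already sits at the
        # finite-difference noise floor
        converged = bool(res.success) or (
            res.status == 2 and np.linalg.norm(res.jac) < 1e-4 * (1 + abs(res.fun))
        )
        k = res.x.size
        cov_theta = np.full((k, k), np.nan)
        try:
            hess = approx_hess(res.x, nll)
            if np.all(np.linalg.eigvalsh(hess) > 0):
                cov_theta = np.linalg.inv(hess)
            else:
                converged = False
        except np.linalg.LinAlgError:
            converged = False
        params = self._unpack(res.x)
        names = PARAM_NAMES[:5]
        if not self.exogenous_observed:
            names = names + ["mu_x", "mu_z", "var_x", "var_z"]
            if self.estimate_exo_correlation:
                names = names + ["cov_xz"]
        J = self._natural_jacobian(res.x, outcome_only)
        cov_nat = J @ cov_theta @ J.T
        return TobitModRegMLResults(self, params, names, cov_nat, converged,
                                    -res.fun)

    def _natural_jacobian(self, theta, outcome_only):
        k = theta.size
        J = np.eye(k)
        J[4, 4] = np.exp(theta[4])  # sigma_e2
        if not outcome_only and not self.exogenous_observed:
            J[7, 7] = np.exp(theta[7])
            J[8, 8] = np.exp(theta[8])
            if self.estimate_exo_correlation and k == 10:
                vx, vz = np.exp(theta[7]), np.exp(theta[8])
                r = np.tanh(theta[9])
                c = r * np.sqrt(vx * vz)
                J[9, 7] = c / 2.0
                J[9, 8] = c / 2.0
                J[9, 9] = (1.0 - r * r) * np.sqrt(vx * vz)
        return J

    # -- Bayes ------------------------------------------------------------
    def fit_bayes(self, **kwargs):
        """Gibbs sampling with augmentation of censored y*, x*, z*; see
        :func:`tobitkit.modreg_bayes.gibbs_modreg_tobit` for options."""
        from .modreg_bayes import TobitModRegBayesResults, gibbs_modreg_tobit

        chains = gibbs_modreg_tobit(self.data, **kwargs)
        return TobitModRegBayesResults(self, chains)


class TobitModRegMLResults:
    """ML estimates with observed-information standard errors."""

    def __init__(self, model, params, param_names, cov_params, converged, llf):
        self.model = model
        self.params: ModRegParams = params
        self.param_names = list(param_names)
        self.cov_params = cov_params
        self.converged = bool(converged)
        self.llf = float(llf)
        self.nobs = model.data.n

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_params), 0.0, None))

    @property
    def beta_cov(self) -> np.ndarray:
        return self.cov_params[:4, :4]

    def wald(self, reference: str = "normal") -> pd.DataFrame:
        """Per-coefficient Wald tests for the regression terms; standard
        normal reference by default, t(n-4) optionally."""
        est = self.params.beta
        se = self.bse[:4]
        stat = est / se
        if reference == "normal":
            p = 2.0 * norm.sf(np.abs(stat))
            crit = norm.ppf(0.975)
            df = np.inf
        elif reference == "t":
            from scipy.stats import t as tdist

            df = self.nobs - 4
            p = 2.0 * tdist.sf(np.abs(stat), df)
            crit = tdist.ppf(0.975, df)
        else:
            raise ValueError("reference must be 'normal' or 't'")
        return pd.DataFrame(
            {
                "estimate": est,
                "se": se,
                "stat": stat,
                "df": df,
                "p": p,
                "ci_lo": est - crit * se,
                "ci_hi": est + crit * se,
            },
            index=list(TERMS),
        )

    def simple_slope(self, z_value: float) -> tuple[float, float]:
        class _View:
            params = self.params.beta
            cov_params = self.beta_cov

        return simple_slope(_View, z_value)

    def summary(self) -> pd.DataFrame:
        full = self.params.as_array()
        est = [full[PARAM_NAMES.index(n)] for n in self.param_names]
        return pd.DataFrame({"estimate": est, "se": self.bse},
                            index=self.param_names)


# -- functional entry points ----------------------------------------------

def modreg_censored_loglik(params: ModRegParams, data: ModRegData,
                           quadrature_nodes: int = 40) -> float:
    model = TobitModeratedRegression(data, quadrature_nodes=quadrature_nodes)
    return model.loglike(params)


def tobit_regression_outcome_only(data: ModRegData) -> TobitModRegMLResults:
    """Classical Tobit regression: censoring in the outcome only."""
    if not (data.x.bounds.unbounded and data.z.bounds.unbounded):
        raise ValueError("x and z must be fully observed for this path")
    if not data.y.is_interior.any():
        raise ValueError("all outcome values are censored")
    return TobitModeratedRegression(data).fit()


def fit_modreg_tobit_ml(data: ModRegData,
                        quadrature_nodes: int = 40,
                        **kwargs) -> TobitModRegMLResults:
    return TobitModeratedRegression(
        data, quadrature_nodes=quadrature_nodes
    ).fit(**kwargs)


def wald_inference(fit: TobitModRegMLResults, n: int | None = None,
                   reference: str = "normal") -> pd.DataFrame:
    return fit.wald(reference)
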