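"""Maximum-likelihood Tobit dependent-sample t-test.

The pre/post true scores are modelled as bivariate normal with mean
(mu1, mu2) and covariance [[v1, c], [c, v2]]; observed scores are the true
scores clipped at the floor/ceiling.  The likelihood is the marginal
censored-bivariate-normal form: density for interior pairs, density times a
conditional tail probability when one coordinate is censored, and a
bivariate rectangle (quadrant) probability when both are.  This is the
moment-level equivalent of the single-common-factor parameterisation
y*_t = alpha_t + lambda_t * eta + eps_t with equal unique variances, whose
(lambda, sigma_e^2) solution is recovered post hoc from the fitted moments
(avoiding the loadings' sign indeterminacy).

The mean-difference t statistic divides mu2_hat - mu1_hat by its
observed-information standard error (default) or by the model-implied
sqrt((v1_hat + v2_hat - 2 c_hat) / N); the two coincide without censoring,
but under censoring only the information SE keeps coverage nominal.  The
reference distribution is t(N-1) by default (or the standard normal), and
Cohen's d is the model-implied standardised difference
(mu2_hat - mu1_hat) / sqrt(v1_hat + v2_hat - 2 c_hat).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.special import log_ndtr
from scipy.stats import norm
from statsmodels.tools.numdiff import approx_hess

from ._bvn import bvn_logpdf, rectangle_prob
from .censoring import CEILING, FLOOR, INTERIOR, PairedSample
from .conventional import PairedTTestResult, _ttest_from_moments

__all__ = [
    "PairedTobitParams",
    "FactorSolution",
    "factor_solution",
    "censored_paired_loglik",
    "TobitPairedTTest",
    "TobitPairedMLResults",
    "fit_paired_tobit_ml",
    "paired_tobit_ttest",
]

PARAM_NAMES = ("mu1", "mu2", "var1", "var2", "cov")


@dataclass
class PairedTobitParams:
    """Mean/covariance parameterisation of the true-score bivariate normal."""

    mu1: float
    mu2: float
    var1: float
    var2: float
    cov: float

    def __post_init__(self) -> None:
        if self.var1 <= 0 or self.var2 <= 0 or self.det <= 0:
            raise ValueError("covariance matrix is not positive definite")

    @property
    def det(self) -> float:
        return self.var1 * self.var2 - self.cov**2

    @property
    def corr(self) -> float:
        return self.cov / np.sqrt(self.var1 * self.var2)

    @property
    def mean_diff(self) -> float:
        return self.mu2 - self.mu1

    @property
    def diff_variance(self) -> float:
        """Variance of the true difference scores, v1 + v2 - 2c."""
        return self.var1 + self.var2 - 2.0 * self.cov

    def as_array(self) -> np.ndarray:
        return np.array([self.mu1, self.mu2, self.var1, self.var2, self.cov])


@dataclass
class FactorSolution:
    """Single-common-factor solution (lambda1, lambda2, sigma_e^2) implied by
    the fitted moments, when it exists."""

    lambda1: float
    lambda2: float
    sigma_e2: float
    exists: bool


def factor_solution(params: PairedTobitParams) -> FactorSolution:
    """Recover (lambda1, lambda2, sigma_e2) from (v1, v2, c).

    sigma_e2 is the smaller root of s^2 - (v1+v2) s + (v1 v2 - c^2) = 0,
    i.e. the equal unique variance; lambda1 = sqrt(v1 - s), lambda2 = c /
    lambda1 (sign-consistent).  Reports exists=False when no real solution
    reproduces the moments.
    """
    v1, v2, c = params.var1, params.var2, params.cov
    disc = (v1 - v2) ** 2 + 4.0 * c * c
    s = 0.5 * ((v1 + v2) - np.sqrt(disc))
    # one Newton step on (v1-s)(v2-s) - c^2 polishes the root to machine
    # precision (matters when c is tiny and v1-s underflows the identity)
    fprime = 2.0 * s - (v1 + v2)
    if fprime != 0.0:
        s -= ((v1 - s) * (v2 - s) - c * c) / fprime
    if s < -1e-12 or s > min(v1, v2) + 1e-12:
        return FactorSolution(np.nan, np.nan, np.nan, False)
    s = float(np.clip(s, 0.0, min(v1, v2)))
    lam1_sq = v1 - s
    if lam1_sq <= 1e-14 and abs(c) > 1e-7:
        return FactorSolution(np.nan, np.nan, s, False)
    # lam2 from v2 - s (not c / lam1): near c = 0 the ratio amplifies the
    # root's floating-point error; the quadratic identity makes
    # sqrt((v1-s)(v2-s)) equal |c| either way
    lam1 = float(np.sqrt(max(lam1_sq, 0.0)))
    lam2 = float(np.copysign(np.sqrt(max(v2 - s, 0.0)), c) if c != 0
                 else np.sqrt(max(v2 - s, 0.0)))
    return FactorSolution(lam1, lam2, s, True)


def censored_paired_loglik(params: PairedTobitParams, data: PairedSample) -> float:
    """Log-likelihood of a paired sample under the censored bivariate normal.

    Subjects with both scores interior contribute the bivariate density;
    one censored score contributes the interior density times the
    conditional tail/head probability; both censored contribute the
    rectangle probability of the censored quadrant.
    """
    mu1, mu2 = params.mu1, params.mu2
    v1, v2, c = params.var1, params.var2, params.cov
    if params.det <= 0:
        raise ValueError("covariance matrix is not positive definite")
    s1, s2 = np.sqrt(v1), np.sqrt(v2)
    rho = c / (s1 * s2)
    y1, y2 = data.pre.values, data.post.values
    st1, st2 = data.pre.status, data.post.status
    b_pre, b_post = data.pre.bounds, data.post.bounds

    ll = 0.0
    both_int = (st1 == INTERIOR) & (st2 == INTERIOR)
    if both_int.any():
        ll += float(
            np.sum(bvn_logpdf(y1[both_int], y2[both_int], mu1, mu2, v1, v2, c))
        )

    # exactly one coordinate censored: density x conditional tail probability
    for cens_first in (True, False):
        if cens_first:
            mask = (st1 != INTERIOR) & (st2 == INTERIOR)
            st_c, y_int = st1[mask], y2[mask]
            mu_c, mu_i, v_c, v_i = mu1, mu2, v1, v2
            bounds_c = b_pre
        else:
            mask = (st2 != INTERIOR) & (st1 == INTERIOR)
            st_c, y_int = st2[mask], y1[mask]
            mu_c, mu_i, v_c, v_i = mu2, mu1, v2, v1
            bounds_c = b_post
        if not mask.any():
            continue
        ll += float(
            np.sum(norm.logpdf(y_int, loc=mu_i, scale=np.sqrt(v_i)))
        )
        cond_mean = mu_c + (c / v_i) * (y_int - mu_i)
        cond_sd = np.sqrt(v_c - c * c / v_i)
        at_ceiling = st_c == CEILING
        zc = np.where(
            at_ceiling,
            (cond_mean - bounds_c.ceiling) / cond_sd,
            (bounds_c.floor - cond_mean) / cond_sd,
        )
        ll += float(np.sum(log_ndtr(zc)))

    # both censored: quadrant probabilities, identical within a corner type
    both_cens = (st1 != INTERIOR) & (st2 != INTERIOR)
    if both_cens.any():
        for code1 in (FLOOR, CEILING):
            for code2 in (FLOOR, CEILING):
                count = int(np.sum(both_cens & (st1 == code1) & (st2 == code2)))
                if count == 0:
                    continue
                if code1 == FLOOR:
                    lo1, hi1 = -np.inf, (b_pre.floor - mu1) / s1
                else:
                    lo1, hi1 = (b_pre.ceiling - mu1) / s1, np.inf
                if code2 == FLOOR:
                    lo2, hi2 = -np.inf, (b_post.floor - mu2) / s2
                else:
                    lo2, hi2 = (b_post.ceiling - mu2) / s2, np.inf
                p = rectangle_prob(lo1, hi1, lo2, hi2, rho)
                ll += count * float(np.log(max(p, 1e-300)))
    return ll


def _unpack(theta: np.ndarray) -> PairedTobitParams:
    mu1, mu2, lv1, lv2, zr = theta
    v1, v2 = np.exp(lv1), np.exp(lv2)
    r = np.tanh(zr)
    return PairedTobitParams(mu1, mu2, v1, v2, r * np.sqrt(v1 * v2))


def _pack(params: PairedTobitParams) -> np.ndarray:
    r = np.clip(params.corr, -0.99, 0.99)
    return np.array(
        [params.mu1, params.mu2, np.log(params.var1), np.log(params.var2),
         np.arctanh(r)]
    )


class TobitPairedMLResults:
    """ML estimates, their covariance, and mean-difference inference."""

    def __init__(self, model, params, cov_params, converged, llf, start_llf):
        self.model = model
        self.params: PairedTobitParams = params
        self.cov_params = cov_params  # 5x5, natural (mu, var, cov) scale
        self.converged = bool(converged)
        self.llf = float(llf)
        self.start_llf = float(start_llf)
        self.nobs = model.data.n

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_params), 0.0, None))

    def ttest(self, reference: str = "t",
              se: str = "information") -> PairedTTestResult:
        """Mean-difference t-test; reference 't' (N-1 df) or 'normal'.

        se='information' (default) uses the observed-information standard
        error of mu2_hat - mu1_hat, which keeps coverage nominal under
        censoring (clipped observations carry less information than the
        model-implied difference-score variance suggests).  se='model' uses
        the model-implied denominator sqrt((v1+v2-2c)/N); the two coincide
        without censoring.  Cohen's d is the effect size
        mean_diff / sqrt(v1+v2-2c) under either choice.
        """
        return paired_tobit_ttest(self.params, self.nobs, reference,
                                  cov_params=self.cov_params if
                                  se == "information" else None)

    def factor_solution(self) -> FactorSolution:
        return factor_solution(self.params)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.params.as_array(), "se": self.bse},
            index=list(PARAM_NAMES),
        )


class TobitPairedTTest:
    """Tobit dependent-sample t-test model (ML or Bayesian estimation).

    Requires at least one interior observation in each occasion — a fully
    censored variable leaves its mean and variance unidentified.
    """

    def __init__(self, data: PairedSample):
        if not data.pre.is_interior.any() or not data.post.is_interior.any():
            raise ValueError(
                "each variable needs at least one interior observation"
            )
        self.data = data

    # -- ML ---------------------------------------------------------------
    def loglike(self, params: PairedTobitParams) -> float:
        return censored_paired_loglik(params, self.data)

    def start_params(self) -> PairedTobitParams:
        """Conventional moments of the observed (censored-included) data."""
        y1, y2 = self.data.pre.values, self.data.post.values
        v1 = max(np.var(y1), 1e-6)
        v2 = max(np.var(y2), 1e-6)
        c = float(np.cov(y1, y2, ddof=0)[0, 1])
        r = np.clip(c / np.sqrt(v1 * v2), -0.95, 0.95)
        return PairedTobitParams(
            float(np.mean(y1)), float(np.mean(y2)), v1, v2, r * np.sqrt(v1 * v2)
        )

    def fit(self, start: PairedTobitParams | None = None,
            gtol: float = 1e-8) -> TobitPairedMLResults:
        start = start or self.start_params()
        theta0 = _pack(start)
        start_llf = self.loglike(start)

        def nll(theta):
            try:
                return -censored_paired_loglik(_unpack(theta), self.data)
            except (ValueError, FloatingPointError):
                return 1e12

        res = minimize(nll, theta0, method="BFGS",
                       options={"gtol": gtol, "maxiter": 500})
        params = _unpack(res.x)
        # "precision loss" with a near-zero finite-difference gradient is a
        # solved problem, not a failure: the gtol sits below the numerical-
        # gradient noise floor
        converged = bool(res.success) or (
            res.status == 2 and np.linalg.norm(res.jac) < 1e-4 * (1 + abs(res.fun))
        )
        cov_nat = np.full((5, 5), np.nan)
        try:
            hess = approx_hess(res.x, nll)
            eigvals = np.linalg.eigvalsh(hess)
            if np.all(eigvals > 0):
                cov_theta = np.linalg.inv(hess)
                J = self._jacobian(res.x)
                cov_nat = J @ cov_theta @ J.T
            else:
                converged = False
        except np.linalg.LinAlgError:
            converged = False
        return TobitPairedMLResults(
            self, params, cov_nat, converged, -res.fun, start_llf
        )

    @staticmethod
    def _jacobian(theta: np.ndarray) -> np.ndarray:
        """d(natural params)/d(transformed params) for the delta method."""
        _, _, lv1, lv2, zr = theta
        v1, v2 = np.exp(lv1), np.exp(lv2)
        r = np.tanh(zr)
        c = r * np.sqrt(v1 * v2)
        J = np.zeros((5, 5))
        J[0, 0] = J[1, 1] = 1.0
        J[2, 2] = v1
        J[3, 3] = v2
        J[4, 2] = c / 2.0
        J[4, 3] = c / 2.0
        J[4, 4] = (1.0 - r * r) * np.sqrt(v1 * v2)
        return J

    # -- Bayes ------------------------------------------------------------
    def fit_bayes(self, **kwargs):
        """Gibbs sampling with data augmentation; see
        :func:`tobitkit.paired_bayes.gibbs_paired_tobit` for options."""
        from .paired_bayes import TobitPairedBayesResults, gibbs_paired_tobit

        chains = gibbs_paired_tobit(self.data, **kwargs)
        return TobitPairedBayesResults(self, chains)


def fit_paired_tobit_ml(data: PairedSample, **kwargs) -> TobitPairedMLResults:
    """Functional entry point for the ML fit."""
    return TobitPairedTTest(data).fit(**kwargs)


def paired_tobit_ttest(
    params: PairedTobitParams,
    n: int,
    reference: str = "t",
    cov_params: np.ndarray | None = None,
) -> PairedTTestResult:
    """Mean-difference t-test from fitted Tobit parameters.

    With ``cov_params`` (the 5x5 estimate covariance) the statistic uses
    the observed-information SE of the mean difference; otherwise the
    model-implied denominator sqrt((v1+v2-2c)/n).  Cohen's d is always the
    model-implied standardised difference mean_diff / sqrt(v1+v2-2c).
    """
    base = _ttest_from_moments(
        params.mean_diff, params.diff_variance, n, reference
    )
    if cov_params is None:
        return base
    grad = np.array([-1.0, 1.0, 0.0, 0.0, 0.0])
    var = float(grad @ np.asarray(cov_params) @ grad)
    if not var > 0:
        raise ValueError("estimate covariance is not positive for the "
                         "mean difference")
    se = float(np.sqrt(var))
    t = params.mean_diff / se
    if reference == "t":
        df = n - 1
        p = 2.0 * stats.t.sf(abs(t), df)
        crit = stats.t.ppf(0.975, df)
    else:
        df = np.inf
        p = 2.0 * stats.norm.sf(abs(t))
        crit = stats.norm.ppf(0.975)
    return PairedTTestResult(
        mean_diff=float(params.mean_diff),
        se=se,
        t_stat=float(t),
        df=float(df),
        p_value=float(p),
        ci95=(float(params.mean_diff - crit * se),
              float(params.mean_diff + crit * se)),
        cohens_d=base.cohens_d,
        reference=reference,
        n=n,
    )
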