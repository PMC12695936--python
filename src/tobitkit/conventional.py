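"""Censoring-ignoring comparators: paired t-test and OLS moderated regression.

These treat observed (possibly ceiling/floor-clipped) scores as if they were
true scores — the baseline against which the Tobit models are evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .censoring import ModRegData, PairedSample

__all__ = [
    "PairedTTestResult",
    "PairedTTest",
    "ModeratedRegressionResults",
    "ModeratedRegression",
    "simple_slope",
]

TERMS = ("intercept", "focal", "moderator", "interaction")


@dataclass
class PairedTTestResult:
    """Mean-difference inference for two correlated samples.

    ``t = (ybar2 - ybar1) / sqrt((s1^2 + s2^2 - 2 s12) / N)`` with N-1
    degrees of freedom (or a standard-normal reference), and Cohen's
    d = t / sqrt(N), the mean difference in units of the SD of the
    difference scores.
    """

    mean_diff: float
    se: float
    t_stat: float
    df: float
    p_value: float
    ci95: tuple[float, float]
    cohens_d: float
    reference: str = "t"
    n: int = 0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": [self.mean_diff],
                "se": [self.se],
                "stat": [self.t_stat],
                "df": [self.df],
                "p": [self.p_value],
                "ci_lo": [self.ci95[0]],
                "ci_hi": [self.ci95[1]],
                "cohens_d": [self.cohens_d],
            },
            index=["mean_diff"],
        )


def _ttest_from_moments(
    mean_diff: float, diff_var: float, n: int, reference: str
) -> PairedTTestResult:
    """Shared t construction: diff_var is the (model or sample) variance of
    difference scores; the denominator is sqrt(diff_var / n)."""
    if diff_var <= 0:
        raise ValueError("variance of the differences is not positive")
    se = float(np.sqrt(diff_var / n))
    t = mean_diff / se
    if reference == "t":
        df = n - 1
        p = 2.0 * stats.t.sf(abs(t), df)
        crit = stats.t.ppf(0.975, df)
    elif reference == "normal":
        df = np.inf
        p = 2.0 * stats.norm.sf(abs(t))
        crit = stats.norm.ppf(0.975)
    else:
        raise ValueError("reference must be 't' or 'normal'")
    return PairedTTestResult(
        mean_diff=float(mean_diff),
        se=se,
        t_stat=float(t),
        df=float(df),
        p_value=float(p),
        ci95=(float(mean_diff - crit * se), float(mean_diff + crit * se)),
        cohens_d=float(t / np.sqrt(n)),
        reference=reference,
        n=n,
    )


class PairedTTest:
    """Classical dependent-sample t-test on the observed scores."""

    def __init__(self, data: PairedSample):
        self.data = data

    def fit(
        self, variance_denominator: str = "n_minus_1", reference: str = "t"
    ) -> PairedTTestResult:
        """Run the test.

        variance_denominator selects the sample-moment convention: the usual
        unbiased n-1 divisor, or 1/N (under which the no-censoring Tobit ML
        t statistic coincides with this one exactly).
        """
        n = self.data.n
        if n < 2:
            raise ValueError("need at least two pairs")
        y1 = self.data.pre.values
        y2 = self.data.post.values
        ddof = 1 if variance_denominator in ("n_minus_1", "n-1") else 0
        if variance_denominator not in ("n_minus_1", "n-1", "n"):
            raise ValueError("variance_denominator must be 'n_minus_1' or 'n'")
        s1 = np.var(y1, ddof=ddof)
        s2 = np.var(y2, ddof=ddof)
        s12 = np.cov(y1, y2, ddof=ddof)[0, 1]
        return _ttest_from_moments(
            float(np.mean(y2) - np.mean(y1)), s1 + s2 - 2.0 * s12, n, reference
        )


class ModeratedRegressionResults:
    """OLS fit of ``y = b0 + b1 x + b2 z + b3 x z + e`` on observed scores."""

    def __init__(self, sm_results):
        self._res = sm_results
        self.params = np.asarray(sm_results.params)
        self.bse = np.asarray(sm_results.bse)
        self.tvalues = np.asarray(sm_results.tvalues)
        self.pvalues = np.asarray(sm_results.pvalues)
        self.df_resid = float(sm_results.df_resid)
        self.sigma2 = float(sm_results.scale)  # SSR / (n - 4)
        self.cov_params = np.asarray(sm_results.cov_params())

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        return np.asarray(self._res.conf_int(alpha))

    def simple_slope(self, z_value: float) -> tuple[float, float]:
        return simple_slope(self, z_value)

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "stat": self.tvalues,
                "df": self.df_resid,
                "p": self.pvalues,
                "ci_lo": ci[:, 0],
                "ci_hi": ci[:, 1],
            },
            index=list(TERMS),
        )


class ModeratedRegression:
    """Conventional (censoring-ignoring) moderated regression via OLS."""

    def __init__(self, data: ModRegData):
        self.data = data

    def fit(self) -> ModeratedRegressionResults:
        n = self.data.n
        if n <= 4:
            raise ValueError("need more than 4 observations")
        x = self.data.x.values
        z = self.data.z.values
        exog = np.column_stack([np.ones(n), x, z, x * z])
        if np.linalg.matrix_rank(exog) < 4:
            raise ValueError("design matrix is rank deficient")
        res = sm.OLS(self.data.y.values, exog).fit()
        return ModeratedRegressionResults(res)


def simple_slope(result, z_value: float) -> tuple[float, float]:
    """Focal-predictor effect ``b1 + b3 z`` at a moderator value, with its
    delta-method SE from the coefficient covariance."""
    b = np.asarray(result.params)
    V = np.asarray(result.cov_params)
    est = b[1] + b[3] * z_value
    var = V[1, 1] + z_value**2 * V[3, 3] + 2.0 * z_value * V[1, 3]
    return float(est), float(np.sqrt(var))
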