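"""Shared MCMC machinery: priors, chain containers, PSRF, truncated normals.

The Gibbs samplers in this package use data augmentation: latent true scores
for censored cells are drawn from truncated-normal full conditionals, after
which every model parameter has a conjugate (normal or gamma) update.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

__all__ = [
    "PriorSpec",
    "PosteriorChains",
    "psrf",
    "sample_truncated_normal",
    "slice_sample",
    "percentile_interval",
]


@dataclass(frozen=True)
class PriorSpec:
    """Diffuse priors: N(0, mean_prior_variance) on location parameters and
    Gamma(shape, rate) on precisions (equivalently inverse-gamma on
    variances)."""

    mean_prior_variance: float = 1e6
    variance_prior_shape: float = 0.001
    variance_prior_rate: float = 0.001

    def __post_init__(self) -> None:
        if min(
            self.mean_prior_variance,
            self.variance_prior_shape,
            self.variance_prior_rate,
        ) <= 0:
            raise ValueError("prior hyperparameters must be positive")


def psrf(draws: np.ndarray) -> float:
    """Gelman–Rubin potential scale reduction factor for one parameter.

    ``draws`` has shape (n_chains, n_kept), post-burn-in only.  Uses the
    classic pooled-variance estimate  Vhat = (n-1)/n * W + B/n  and returns
    sqrt(Vhat / W); values near 1 indicate convergence, > 1.1 is the usual
    nonconvergence flag.
    """
    draws = np.asarray(draws, float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("need draws from at least 2 chains")
    m, n = draws.shape
    if n < 10:
        raise ValueError("need at least 10 post-burn-in draws per chain")
    within = draws.var(axis=1, ddof=1)
    W = within.mean()
    if W <= 0:
        raise ValueError("zero within-chain variance: degenerate chains")
    B_over_n = draws.mean(axis=1).var(ddof=1)
    v_hat = (n - 1) / n * W + B_over_n
    return float(np.sqrt(v_hat / W))


@dataclass
class PosteriorChains:
    """Post-burn-in draws per parameter, indexed (chain, iteration)."""

    draws: dict[str, np.ndarray]
    burn_in: int
    seed: int | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.draws.values()}
        if len(shapes) != 1:
            raise ValueError("all parameters must share the (chain, iter) shape")
        (shape,) = shapes
        if len(shape) != 2 or shape[0] < 2:
            raise ValueError("need at least 2 chains")

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_kept(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    @property
    def parameters(self) -> list[str]:
        return list(self.draws)

    def pooled(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def psrf(self) -> dict[str, float]:
        return {name: psrf(d) for name, d in self.draws.items()}

    @property
    def converged(self) -> bool:
        """True when every parameter has PSRF below 1.1."""
        return all(r < 1.1 for r in self.psrf().values())

    def summary(self, cred: float = 0.95) -> pd.DataFrame:
        rows = []
        rhat = self.psrf()
        for name in self.draws:
            pooled = self.pooled(name)
            lo, hi = percentile_interval(pooled, cred)
            rows.append(
                {
                    "mean": pooled.mean(),
                    "sd": pooled.std(ddof=1),
                    "ci_lo": lo,
                    "ci_hi": hi,
                    "psrf": rhat[name],
                }
            )
        return pd.DataFrame(rows, index=list(self.draws))

    def plot_trace(self, names=None, axes=None):
        """Trace plots per chain (requires matplotlib)."""
        import matplotlib.pyplot as plt

        names = list(names or self.draws)
        if axes is None:
            _, axes = plt.subplots(len(names), 1, squeeze=False, sharex=True)
            axes = axes[:, 0]
        for ax, name in zip(axes, names):
            for chain in self.draws[name]:
                ax.plot(chain, lw=0.4)
            ax.set_ylabel(name)
        return axes


def percentile_interval(draws: np.ndarray, cred: float = 0.95) -> tuple[float, float]:
    """Equal-tailed percentile interval, linear interpolation between order
    statistics (numpy's default percentile rule)."""
    alpha = 100.0 * (1.0 - cred) / 2.0
    lo, hi = np.percentile(draws, [alpha, 100.0 - alpha])
    return float(lo), float(hi)


def sample_truncated_normal(rng, mean, sd, lower=-np.inf, upper=np.inf):
    """Vectorised truncated-normal draws.

    Inverse-CDF sampling for moderate truncation; one-sided tail regions
    beyond 5 standardised units use Robert's (1995) exponential rejection
    sampler, which stays exact where the CDF difference underflows.
    """
    mean = np.asarray(mean, float)
    sd = np.asarray(sd, float)
    mean, sd, lower, upper = np.broadcast_arrays(
        mean, sd, np.asarray(lower, float), np.asarray(upper, float)
    )
    a = (lower - mean) / sd
    b = (upper - mean) / sd
    out = np.empty(mean.shape)

    tail_lo = a > 5.0  # sampling the far upper tail [a, b)
    tail_hi = b < -5.0  # far lower tail, by symmetry
    mid = ~(tail_lo | tail_hi)

    if mid.any():
        ua = ndtr(a[mid])
        ub = ndtr(b[mid])
        u = ua + (ub - ua) * rng.random(int(mid.sum()))
        # guard the open interval so ndtri stays finite
        u = np.clip(u, 1e-16, 1.0 - 1e-16)
        out[mid] = mean[mid] + sd[mid] * ndtri(u)
    for mask, sign in ((tail_lo, 1.0), (tail_hi, -1.0)):
        if not mask.any():
            continue
        lo = sign * np.where(sign > 0, a[mask], -b[mask])
        hi = np.where(sign > 0, b[mask], -a[mask])  # may be +inf
        z = _robert_tail(rng, lo, hi)
        out[mask] = mean[mask] + sd[mask] * sign * z
    return out


def trunc_norm_lower(rng, mean, sd, lower):
    """Draws of N(mean, sd^2) conditioned on X >= lower (vectorised, lean).

    Inverse-CDF for moderate truncation; Robert's rejection sampler beyond
    5 standardised units, where the CDF difference underflows.
    """
    mean = np.asarray(mean, float)
    a = (np.asarray(lower, float) - mean) / sd
    out = np.empty(a.shape)
    far = a > 5.0
    if far.any():
        out[far] = mean[far] + sd * _robert_tail(
            rng, a[far], np.full(int(far.sum()), np.inf)
        )
    near = ~far
    ua = ndtr(a[near])
    u = np.clip(ua + (1.0 - ua) * rng.random(int(near.sum())),
                1e-16, 1.0 - 1e-16)
    out[near] = mean[near] + sd * ndtri(u)
    return out


def trunc_norm_upper(rng, mean, sd, upper):
    """Draws of N(mean, sd^2) conditioned on X <= upper (by symmetry)."""
    mean = np.asarray(mean, float)
    return 2.0 * mean - trunc_norm_lower(rng, mean, sd,
                                         2.0 * mean - np.asarray(upper, float))


def slice_sample(rng, x0: float, logpdf, width: float = 1.0,
                 max_steps: int = 50) -> float:
    """One univariate slice-sampling update (Neal 2003, stepping-out and
    shrinkage).  Used for variance components on the log scale, where the
    marginal conditional is log-concave-ish but not of standard form."""
    logy = logpdf(x0) + np.log(rng.random())
    u = rng.random()
    lo = x0 - width * u
    hi = lo + width
    steps = max_steps
    while steps > 0 and logpdf(lo) > logy:
        lo -= width
        steps -= 1
    steps = max_steps
    while steps > 0 and logpdf(hi) > logy:
        hi += width
        steps -= 1
    while True:
        x1 = lo + (hi - lo) * rng.random()
        if logpdf(x1) > logy:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1


def _robert_tail(rng, lo, hi):
    """Draws from a standard normal truncated to [lo, hi), lo > 0 large."""
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    n = lo.size
    out = np.empty(n)
    todo = np.arange(n)
    alpha = (lo + np.sqrt(lo * lo + 4.0)) / 2.0
    while todo.size:
        l_, h_, al = lo[todo], hi[todo], alpha[todo]
        z = l_ - np.log1p(-rng.random(todo.size)) / al  # shifted exponential
        accept = (z < h_) & (
            rng.random(todo.size) <= np.exp(-0.5 * (z - al) ** 2)
        )
        out[todo[accept]] = z[accept]
        todo = todo[~accept]
    return out
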