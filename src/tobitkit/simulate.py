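"""Synthetic-data generators for the two Monte-Carlo study designs.

Paired design: pre-test true scores y1* ~ N(0, 1), post-test
y2* ~ N(mu2, SDR^2) with correlation rho and
mu2 = d * sqrt(1 + SDR^2 - 2 rho SDR), so d is the population Cohen's d of
the difference scores.  The ceiling threshold is Phi^{-1}(1 - CP) on the
pre-test N(0,1) marginal and is applied unchanged to both occasions (the
post-test ceiling proportion then follows from mu2 and SDR).

Moderated-regression design: (x*, z*) bivariate normal with unit marginals
and correlation rho; y* = x* + z* + beta3 x* z* + e with e ~ N(0, 1)
(intercept 0, unit main effects and residual variance).  Scenario
"xy_censored": x and y share the ceiling Phi^{-1}(1 - CP) taken from X's
N(0,1) marginal; scenario "z_censored": the same rule is applied to z only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .censoring import (
    CensoredVariable,
    CensoringBounds,
    ModRegData,
    PairedSample,
    ceiling_threshold,
)

__all__ = [
    "PairedCondition",
    "ModRegCondition",
    "gen_paired",
    "gen_modreg",
    "true_mean_difference",
    "PAIRED_GRID",
    "MODREG_GRID",
]

# factor levels of the two factorial study designs (2x2x2x4x4 and
# 2x4x2x2x4 = 128 cells each); free values outside the grids are allowed
PAIRED_GRID = {
    "d": (0.0, 0.5),
    "sdr": (1.0, 1.5),
    "rho": (0.0, 0.5),
    "cp": (0.0, 0.1, 0.2, 0.3),
    "n": (50, 100, 200, 500),
}
MODREG_GRID = {
    "scenario": ("xy_censored", "z_censored"),
    "beta3": (0.0, 0.39),
    "rho": (0.0, 0.3),
    "cp": (0.0, 0.1, 0.2, 0.3),
    "n": (50, 100, 200, 500),
}


def true_mean_difference(d: float, sdr: float, rho: float) -> float:
    """Population mean difference mu2 = d sqrt(1 + SDR^2 - 2 rho SDR)."""
    return d * math.sqrt(1.0 + sdr**2 - 2.0 * rho * sdr)


@dataclass(frozen=True)
class PairedCondition:
    """One cell of the paired-design factorial."""

    d: float = 0.0
    sdr: float = 1.0
    rho: float = 0.5
    cp: float = 0.0
    n: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.cp < 1.0:
            raise ValueError("cp must be in [0, 1)")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must be in (-1, 1)")
        if self.sdr <= 0 or self.n < 1:
            raise ValueError("sdr must be positive and n >= 1")

    @property
    def mu2(self) -> float:
        return true_mean_difference(self.d, self.sdr, self.rho)


@dataclass(frozen=True)
class ModRegCondition:
    """One cell of the moderated-regression factorial."""

    scenario: str = "xy_censored"
    beta3: float = 0.0
    rho: float = 0.3
    cp: float = 0.0
    n: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.scenario not in ("xy_censored", "z_censored"):
            raise ValueError("scenario must be 'xy_censored' or 'z_censored'")
        if not 0.0 <= self.cp < 1.0:
            raise ValueError("cp must be in [0, 1)")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must be in (-1, 1)")
        if self.n < 1:
            raise ValueError("n >= 1")

    beta = (0.0, 1.0, 1.0)  # intercept and unit main effects, by design
    sigma_e2 = 1.0


def _rng_for(cond, rng):
    if rng is not None:
        return rng
    return np.random.default_rng(cond.seed)


def gen_paired(cond: PairedCondition, rng=None) -> PairedSample:
    """Draw one replication of the paired design."""
    rng = _rng_for(cond, rng)
    mu2 = cond.mu2
    cov = np.array(
        [[1.0, cond.rho * cond.sdr], [cond.rho * cond.sdr, cond.sdr**2]]
    )
    true = rng.multivariate_normal([0.0, mu2], cov, size=cond.n,
                                   method="cholesky")
    bounds = CensoringBounds(ceiling=ceiling_threshold(cond.cp))
    return PairedSample(
        pre=CensoredVariable.from_true(true[:, 0], bounds),
        post=CensoredVariable.from_true(true[:, 1], bounds),
    )


def gen_modreg(cond: ModRegCondition, rng=None) -> ModRegData:
    """Draw one replication of the moderated-regression design."""
    rng = _rng_for(cond, rng)
    cov = np.array([[1.0, cond.rho], [cond.rho, 1.0]])
    xz = rng.multivariate_normal([0.0, 0.0], cov, size=cond.n,
                                 method="cholesky")
    x, z = xz[:, 0], xz[:, 1]
    y = x + z + cond.beta3 * x * z + rng.standard_normal(cond.n)
    threshold = ceiling_threshold(cond.cp)
    shared = CensoringBounds(ceiling=threshold)
    unbounded = CensoringBounds()
    if cond.scenario == "xy_censored":
        yb, xb, zb = shared, shared, unbounded
    else:
        yb, xb, zb = unbounded, unbounded, shared
    return ModRegData(
        y=CensoredVariable.from_true(y, yb),
        x=CensoredVariable.from_true(x, xb),
        z=CensoredVariable.from_true(z, zb),
    )
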