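"""Censored-variable containers and ceiling/floor utilities.

A ceiling (floor) effect clips latent true scores ``y*`` to the scale
maximum ``b`` (minimum ``a``)::

    y = a    if y* <= a
    y = y*   if a < y* < b
    y = b    if y* >= b

Observations sitting exactly at a bound are treated as censored: the bound
value is a proxy for an unobserved true score at or beyond it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "FLOOR",
    "INTERIOR",
    "CEILING",
    "CensoringBounds",
    "CensoredVariable",
    "PairedSample",
    "ModRegData",
    "censor",
    "ceiling_threshold",
    "floor_threshold",
    "censoring_summary",
]

# per-observation censoring status codes
FLOOR: int = -1
INTERIOR: int = 0
CEILING: int = 1


@dataclass(frozen=True)
class CensoringBounds:
    """Floor/ceiling thresholds ``(a, b)`` for one variable.

    Either bound may be infinite; both infinite means the variable is fully
    observed.
    """

    floor: float = -math.inf
    ceiling: float = math.inf

    def __post_init__(self) -> None:
        if not self.floor < self.ceiling:
            raise ValueError(
                f"floor must be strictly below ceiling, got "
                f"({self.floor}, {self.ceiling})"
            )

    @property
    def unbounded(self) -> bool:
        return math.isinf(self.floor) and math.isinf(self.ceiling)


@dataclass
class CensoredVariable:
    """Observed scores together with their bounds and censoring status.

    ``status[i]`` is ``FLOOR``/``CEILING`` iff ``values[i]`` equals the
    corresponding bound, ``INTERIOR`` otherwise. No missing entries are
    allowed.
    """

    values: np.ndarray
    bounds: CensoringBounds
    status: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.status = np.asarray(self.status, dtype=np.int8)
        if self.values.ndim != 1 or self.values.shape != self.status.shape:
            raise ValueError("values and status must be 1-d arrays of equal length")
        if np.isnan(self.values).any():
            raise ValueError("missing values are not supported")

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_true(cls, true_scores, bounds: CensoringBounds) -> "CensoredVariable":
        """Clip latent true scores to the bounds (the censoring rule)."""
        true_scores = np.asarray(true_scores, dtype=float)
        status = np.zeros(true_scores.shape, dtype=np.int8)
        status[true_scores <= bounds.floor] = FLOOR
        status[true_scores >= bounds.ceiling] = CEILING
        values = np.clip(true_scores, bounds.floor, bounds.ceiling)
        return cls(values=values, bounds=bounds, status=status)

    @classmethod
    def from_observed(
        cls, values, bounds: CensoringBounds, atol: float = 1e-12
    ) -> "CensoredVariable":
        """Ingest already-observed scores, detecting censoring by equality.

        Values strictly outside ``[a, b]`` (beyond ``atol``) indicate a wrong
        threshold specification and are rejected rather than clipped.
        """
        values = np.asarray(values, dtype=float)
        if np.isnan(values).any():
            raise ValueError("missing values are not supported")
        below = values < bounds.floor - atol
        above = values > bounds.ceiling + atol
        if below.any() or above.any():
            bad = values[below | above]
            raise ValueError(
                f"{bad.size} value(s) lie outside the bounds "
                f"({bounds.floor}, {bounds.ceiling}); check the thresholds"
            )
        status = np.zeros(values.shape, dtype=np.int8)
        status[np.abs(values - bounds.floor) <= atol] = FLOOR
        status[np.abs(values - bounds.ceiling) <= atol] = CEILING
        values = values.copy()
        values[status == FLOOR] = bounds.floor
        values[status == CEILING] = bounds.ceiling
        return cls(values=values, bounds=bounds, status=status)

    # -- views -------------------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.size

    @property
    def is_interior(self) -> np.ndarray:
        return self.status == INTERIOR

    @property
    def floor_prop(self) -> float:
        return float(np.mean(self.status == FLOOR))

    @property
    def ceiling_prop(self) -> float:
        return float(np.mean(self.status == CEILING))


def censor(true_scores, bounds: CensoringBounds) -> CensoredVariable:
    """Apply the ceiling/floor censoring rule to latent true scores."""
    return CensoredVariable.from_true(true_scores, bounds)


def ceiling_threshold(cp: float) -> float:
    """Standard-normal ceiling threshold giving ceiling proportion ``cp``.

    Returns ``Phi^{-1}(1 - cp)``; ``cp = 0`` means no ceiling (+inf).
    """
    if not 0.0 <= cp < 1.0:
        raise ValueError(f"ceiling proportion must be in [0, 1), got {cp}")
    if cp == 0.0:
        return math.inf
    return float(norm.ppf(1.0 - cp))


def floor_threshold(fp: float) -> float:
    """Standard-normal floor threshold giving floor proportion ``fp``."""
    if not 0.0 <= fp < 1.0:
        raise ValueError(f"floor proportion must be in [0, 1), got {fp}")
    if fp == 0.0:
        return -math.inf
    return float(norm.ppf(fp))


def censoring_summary(v: CensoredVariable) -> tuple[float, float]:
    """Proportions of observations at the floor and at the ceiling."""
    if v.n == 0:
        raise ValueError("empty variable")
    return v.floor_prop, v.ceiling_prop


@dataclass
class PairedSample:
    """Aligned pre-test/post-test censored measurements on N subjects."""

    pre: CensoredVariable
    post: CensoredVariable

    def __post_init__(self) -> None:
        if self.pre.n != self.post.n:
            raise ValueError("pre and post must have equal length")

    @property
    def n(self) -> int:
        return self.pre.n

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        pre: str,
        post: str,
        floor: float = -math.inf,
        ceiling: float = math.inf,
    ) -> "PairedSample":
        """Build from a headered table; both occasions share one scale."""
        bounds = CensoringBounds(floor, ceiling)
        return cls(
            pre=CensoredVariable.from_observed(df[pre].to_numpy(), bounds),
            post=CensoredVariable.from_observed(df[post].to_numpy(), bounds),
        )


@dataclass
class ModRegData:
    """Outcome / focal predictor / moderator triple, each with own bounds."""

    y: CensoredVariable
    x: CensoredVariable
    z: CensoredVariable

    def __post_init__(self) -> None:
        if not (self.y.n == self.x.n == self.z.n):
            raise ValueError("y, x, z must have equal length")

    @property
    def n(self) -> int:
        return self.y.n

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        y: str,
        x: str,
        z: str,
        y_bounds: CensoringBounds | None = None,
        x_bounds: CensoringBounds | None = None,
        z_bounds: CensoringBounds | None = None,
    ) -> "ModRegData":
        unbounded = CensoringBounds()
        return cls(
            y=CensoredVariable.from_observed(df[y].to_numpy(), y_bounds or unbounded),
            x=CensoredVariable.from_observed(df[x].to_numpy(), x_bounds or unbounded),
            z=CensoredVariable.from_observed(df[z].to_numpy(), z_bounds or unbounded),
        )
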