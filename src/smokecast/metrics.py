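"""Forecast verification metrics.

The verification suite used throughout the package: root mean square error
(RMSE), Willmott's index of agreement (IOA), the fraction of forecasts within
a relative tolerance of the observation, population rates and population
weighting, percent change, and Pearson correlation.

The index of agreement is

    IOA = 1 - sum_i (P_i - O_i)^2 / sum_i (|P_i - Obar| + |O_i - Obar|)^2

where ``P`` are predictions, ``O`` observations and ``Obar`` the observation
mean.  It is bounded on [0, 1]: 0 indicates no agreement (e.g. every forecast
equal to the observation mean of a non-constant series) and 1 perfect
agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedSeries",
    "EvalSummary",
    "rmse",
    "ioa",
    "pct_within",
    "rate_per_10k",
    "percent_change",
    "pop_weighted_metric",
    "pearson",
]


@dataclass
class PairedSeries:
    """A prediction series aligned with its observation series.

    Construct directly from equal-length arrays, or with :meth:`align` from
    two date-indexed series (dates missing from either side are dropped and
    counted in ``n_dropped``).
    """

    P: np.ndarray
    O: np.ndarray
    dates: np.ndarray | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.O = np.asarray(self.O, dtype=float)
        if self.P.shape != self.O.shape or self.P.ndim != 1:
            raise ValueError("P and O must be 1-d arrays of equal length")
        if len(self.P) == 0:
            raise ValueError("empty paired series")
        if np.isnan(self.P).any() or np.isnan(self.O).any():
            raise ValueError("paired series contains missing values; use align()")

    @classmethod
    def align(cls, predictions: pd.Series, observations: pd.Series) -> "PairedSeries":
        joined = pd.concat({"P": predictions, "O": observations}, axis=1)
        clean = joined.dropna()
        return cls(
            P=clean["P"].to_numpy(float),
            O=clean["O"].to_numpy(float),
            dates=clean.index.to_numpy(),
            n_dropped=len(joined) - len(clean),
        )

    @property
    def n(self) -> int:
        return len(self.P)


@dataclass
class EvalSummary:
    """Per-health-area verification summary for one forecast horizon."""

    hsda_id: str
    horizon: str  # "day0" | "day1" | "both"
    n_forecasts: int
    rmse: float
    ioa: float
    pct_within20: float
    population: int
    rmse_per_10k: float | None = None
    extras: dict = field(default_factory=dict)


def _as_pair(ps) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(ps, PairedSeries):
        return ps.P, ps.O
    P, O = ps
    return np.asarray(P, dtype=float), np.asarray(O, dtype=float)


def rmse(ps) -> float:
    """Root mean square error sqrt(sum (P_i - O_i)^2 / n)."""
    P, O = _as_pair(ps)
    if len(P) == 0:
        raise ValueError("rmse of empty series")
    return float(np.sqrt(np.mean((P - O) ** 2)))


def ioa(ps) -> float:
    """Index of agreement on [0, 1].

    Returns 1.0 when the potential-error denominator is zero, which occurs
    only when predictions and observations are one identical constant.
    """
    P, O = _as_pair(ps)
    if len(P) < 2:
        raise ValueError("ioa requires n >= 2")
    obar = O.mean()
    num = float(np.sum((P - O) ** 2))
    den = float(np.sum((np.abs(P - obar) + np.abs(O - obar)) ** 2))
    if den == 0.0:
        return 1.0
    return 1.0 - num / den


def pct_within(ps, frac: float = 0.2) -> float:
    """Percent of pairs with |P_i - O_i| <= frac * O_i (boundary inclusive).

    A zero observation counts as within tolerance only for a zero prediction.
    """
    P, O = _as_pair(ps)
    if len(P) == 0:
        raise ValueError("pct_within of empty series")
    hit = np.abs(P - O) <= frac * np.abs(O)
    hit[O == 0] = P[O == 0] == 0
    return float(100.0 * hit.mean())


def rate_per_10k(value: float, population: float) -> float:
    """Express a count (or count-scale error) as a rate per 10,000 residents."""
    if population <= 0:
        raise ValueError("population must be positive")
    return float(value * 10_000.0 / population)


def percent_change(current: float, reference: float) -> float:
    """100 * (current - reference) / reference; rounding is the caller's."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return float(100.0 * (current - reference) / reference)


def pop_weighted_metric(values: dict, populations: dict) -> float:
    """Population-weighted mean of a per-region metric."""
    if not values:
        raise ValueError("no values to weight")
    if set(values) != set(populations):
        raise ValueError("values and populations must share the same keys")
    keys = list(values)
    v = np.array([values[k] for k in keys], dtype=float)
    w = np.array([populations[k] for k in keys], dtype=float)
    if (w <= 0).any():
        raise ValueError("populations must be positive")
    return float(np.sum(v * w) / np.sum(w))


def pearson(x, y) -> float:
    """Sample Pearson correlation; rejects series with zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson requires equal-length series with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson undefined for zero-variance series")
    return float(stats.pearsonr(x, y).statistic)
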