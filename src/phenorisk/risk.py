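"""Quasi-extinction (critical decline) risk from (U, Q).

Log-abundance is modeled as Brownian motion with drift U and infinitesimal
variance Q. The probability that the process falls a distance ``a`` below
its current value within horizon T (first passage of the lower barrier) is
the inverse-Gaussian tail

    P_e = Phi(mu - V) + exp(2 mu V) * Phi(-mu - V),
    mu  = -U T / sqrt(Q T),     V = a / sqrt(Q T),

with Phi the standard normal CDF. Equivalently
Phi((-a - UT)/sqrt(QT)) + exp(-2 U a / Q) * Phi((-a + UT)/sqrt(QT)).
The exponential term is evaluated in log space (exp(2 mu V + log Phi))
so extreme parameters (tiny Q, long T) cannot overflow.

A 90% decline corresponds to a = ln(10) on the log scale. Scenario risks
evaluate the same formula at the CI endpoints: best case (U_hi, Q_lo),
worst case (U_lo, Q_hi).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .marfit import DEFAULT_Q_FLOOR, MarFit

__all__ = [
    "RiskQuery",
    "RiskEstimate",
    "quasi_extinction_probability",
    "scenario_risks",
    "risk_trajectory",
    "DECLINE_90_THRESHOLD",
]

#: Log-scale distance of a 90% decline: a = ln(10).
DECLINE_90_THRESHOLD = math.log(10.0)


@dataclass(frozen=True)
class RiskQuery:
    """Decline threshold distance ``a`` (log scale) and horizon ``T`` (years)."""

    a: float = DECLINE_90_THRESHOLD
    T: float = 1.0

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError("threshold distance a must be >= 0")
        if self.T <= 0:
            raise ValueError("horizon T must be positive")


@dataclass
class RiskEstimate:
    """Scenario risks for one stratum at one horizon."""

    taxon: str
    region: str
    month: int
    T: float
    a: float
    p_baseline: float
    p_best: float
    p_worst: float
    mu: float = np.nan
    V: float = np.nan


def quasi_extinction_probability(U, Q, query: RiskQuery):
    """First-passage probability of an ``a``-sized decline within T years.

    ``U`` and ``Q`` may be scalars or broadcastable arrays; Q must be
    strictly positive (use the fit's variance floor for degenerate strata).
    Returns values clamped to [0, 1].
    """
    U = np.asarray(U, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if not (np.all(np.isfinite(U)) and np.all(np.isfinite(Q))):
        raise ValueError("U and Q must be finite")
    if np.any(Q <= 0):
        raise ValueError("process variance Q must be > 0 (apply a variance floor)")
    s = np.sqrt(Q * query.T)
    mu = -U * query.T / s
    V = query.a / s
    with np.errstate(over="ignore", under="ignore"):
        term1 = norm.cdf(mu - V)
        # exp(2*mu*V) * Phi(-mu-V), via logs: 2*mu*V can exceed 700
        log_term2 = 2.0 * mu * V + norm.logcdf(-mu - V)
        term2 = np.exp(log_term2)
    p = np.clip(term1 + term2, 0.0, 1.0)
    return float(p) if p.ndim == 0 else p


def _standardized(U: float, Q: float, query: RiskQuery) -> tuple[float, float]:
    s = math.sqrt(Q * query.T)
    return -U * query.T / s, query.a / s


def scenario_risks(
    fit: MarFit, query: RiskQuery, q_floor: float = DEFAULT_Q_FLOOR
) -> RiskEstimate:
    """Baseline / best-case / worst-case risk for one stratum.

    Baseline uses the ML point estimates (U_hat, Q_hat); best case the
    upper drift and lower variance CI endpoints (U_hi, Q_lo); worst case
    (U_lo, Q_hi). Requires a fit carrying CIs.
    """
    if not fit.has_ci:
        raise ValueError(
            f"fit for taxon={fit.taxon} region={fit.region} month={fit.month} "
            "carries no confidence intervals"
        )
    qb = max(fit.Q_hat, q_floor)
    mu, V = _standardized(fit.U_hat, qb, query)
    return RiskEstimate(
        taxon=fit.taxon,
        region=fit.region,
        month=fit.month,
        T=query.T,
        a=query.a,
        p_baseline=quasi_extinction_probability(fit.U_hat, qb, query),
        p_best=quasi_extinction_probability(fit.U_hi, max(fit.Q_lo, q_floor), query),
        p_worst=quasi_extinction_probability(fit.U_lo, max(fit.Q_hi, q_floor), query),
        mu=mu,
        V=V,
    )


def risk_trajectory(
    fit: MarFit,
    a: float = DECLINE_90_THRESHOLD,
    horizons: Sequence[float] = tuple(range(1, 11)),
    q_floor: float = DEFAULT_Q_FLOOR,
) -> list[RiskEstimate]:
    """Scenario risks over a sequence of horizons (baseline non-decreasing in T)."""
    if len(horizons) < 1:
        raise ValueError("at least one horizon required")
    return [scenario_risks(fit, RiskQuery(a=a, T=T), q_floor=q_floor) for T in horizons]
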