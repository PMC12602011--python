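"""Maximum-likelihood drift and process-variance estimation.

Model: each station's month-specific annual series follows a random walk
with drift, X_t = X_{t-1} + U + W_t, W_t ~ N(0, Q), with one drift U and
one process variance Q shared across the stations of a region (station
increments independent). Missing survey years are handled exactly: the
difference across a gap of k years is N(kU, kQ).

The joint Gaussian MLE has a closed form on the gap-differences:

    U_hat = sum(delta_i) / sum(k_i)              (independent of Q)
    Q_hat = mean((delta_i - k_i U_hat)^2 / k_i)  (n-denominator MLE)

Confidence intervals come from a parametric bootstrap that re-simulates
the differences under (U_hat, Q_hat) with the identical span pattern —
equivalent to simulating series with the identical observation/missing
pattern — and refits each replicate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .survey import MonthSeries

__all__ = [
    "GapDifference",
    "MarFit",
    "extract_differences",
    "fit_drift_variance",
    "bootstrap_ci",
    "fit_stratum",
    "DEFAULT_Q_FLOOR",
    "DEFAULT_BOOTSTRAP_B",
]

logger = logging.getLogger(__name__)

#: Variance floor (log^2 scale) keeping the risk formula defined for
#: noise-free series.
DEFAULT_Q_FLOOR = 1e-10
#: Parametric-bootstrap replicates for the 95% CIs.
DEFAULT_BOOTSTRAP_B = 1000


@dataclass(frozen=True)
class GapDifference:
    """Difference of log-CPUE across ``span_k`` years at one station."""

    station: str
    span_k: int
    delta: float

    def __post_init__(self) -> None:
        if self.span_k < 1:
            raise ValueError("span_k must be >= 1")
        if not np.isfinite(self.delta):
            raise ValueError("delta must be finite")


@dataclass
class MarFit:
    """Drift/variance fit for one taxon x region x month stratum."""

    taxon: str
    region: str
    month: int
    U_hat: float
    Q_hat: float
    U_lo: float = np.nan
    U_hi: float = np.nan
    Q_lo: float = np.nan
    Q_hi: float = np.nan
    n_diffs: int = 0
    n_stations: int = 0
    degenerate: bool = False
    seed: int | None = None
    B: int = 0

    @property
    def has_ci(self) -> bool:
        return np.isfinite([self.U_lo, self.U_hi, self.Q_lo, self.Q_hi]).all()

    def collapsed_ci(self) -> "MarFit":
        """Copy with the CIs collapsed onto the point estimates."""
        return replace(
            self, U_lo=self.U_hat, U_hi=self.U_hat, Q_lo=self.Q_hat, Q_hi=self.Q_hat
        )


def extract_differences(
    series_group: Iterable[MonthSeries],
) -> list[GapDifference]:
    """Gap-aware first differences pooled across the stations of a stratum.

    Per station, one difference per adjacent pair of *observed* years;
    ``span_k`` is the year gap. Stations with fewer than 2 observed years
    contribute nothing (logged).
    """
    diffs: list[GapDifference] = []
    for s in series_group:
        yrs = s.years[s.observed]
        vals = s.values[s.observed]
        if len(yrs) < 2:
            logger.info(
                "station %s (taxon=%s month=%d) has <2 observed years; no "
                "differences", s.station, s.taxon, s.month,
            )
            continue
        spans = np.diff(yrs)
        deltas = np.diff(vals)
        diffs.extend(
            GapDifference(s.station, int(k), float(d))
            for k, d in zip(spans, deltas)
        )
    return diffs


def _mle(deltas: np.ndarray, spans: np.ndarray) -> tuple[float, float]:
    U = deltas.sum() / spans.sum()
    Q = float(np.mean((deltas - spans * U) ** 2 / spans))
    return float(U), Q


def fit_drift_variance(
    diffs: Sequence[GapDifference],
    q_floor: float = DEFAULT_Q_FLOOR,
    taxon: str = "",
    region: str = "",
    month: int = 1,
) -> MarFit:
    """Closed-form joint MLE of (U, Q) on pooled gap differences.

    With all spans equal to 1 this is the difference mean and the
    n-denominator mean squared deviation. ``Q_hat`` below ``q_floor`` is
    floored and the fit flagged degenerate; a single difference carries no
    variance information and is likewise degenerate.
    """
    if not diffs:
        raise ValueError("no differences to fit")
    deltas = np.array([d.delta for d in diffs])
    spans = np.array([d.span_k for d in diffs], dtype=float)
    U_hat, Q_hat = _mle(deltas, spans)
    degenerate = len(diffs) < 2 or Q_hat < q_floor
    if degenerate:
        Q_hat = max(Q_hat, q_floor)
    return MarFit(
        taxon=taxon,
        region=region,
        month=month,
        U_hat=U_hat,
        Q_hat=Q_hat,
        n_diffs=len(diffs),
        n_stations=len({d.station for d in diffs}),
        degenerate=degenerate,
    )


def bootstrap_ci(
    fit: MarFit,
    diffs: Sequence[GapDifference],
    B: int = DEFAULT_BOOTSTRAP_B,
    seed: int | None = None,
    q_floor: float = DEFAULT_Q_FLOOR,
) -> MarFit:
    """Percentile 95% CIs for (U, Q) by parametric bootstrap.

    Each replicate draws delta*_i ~ N(k_i U_hat, k_i Q_hat) over the
    observed span pattern and refits the closed-form MLE; the CI endpoints
    are the 2.5/97.5 percentiles of the B estimates. Deterministic under a
    fixed seed.
    """
    if not diffs:
        raise ValueError("no differences to bootstrap")
    if B < 100:
        warnings.warn(
            f"B={B} bootstrap replicates give unstable percentile CIs",
            stacklevel=2,
        )
    spans = np.array([d.span_k for d in diffs], dtype=float)
    rng = np.random.default_rng(seed)
    sim = spans * fit.U_hat + rng.normal(
        0.0, np.sqrt(spans * max(fit.Q_hat, q_floor)), size=(B, len(spans))
    )
    U_star = sim.sum(axis=1) / spans.sum()
    Q_star = np.mean((sim - spans * U_star[:, None]) ** 2 / spans, axis=1)
    U_lo, U_hi = np.percentile(U_star, [2.5, 97.5])
    Q_lo, Q_hi = np.percentile(Q_star, [2.5, 97.5])
    out = replace(
        fit,
        U_lo=float(min(U_lo, fit.U_hat)),
        U_hi=float(max(U_hi, fit.U_hat)),
        Q_lo=float(min(Q_lo, fit.Q_hat)),
        Q_hi=float(max(Q_hi, fit.Q_hat)),
        seed=seed,
        B=B,
    )
    return out


def fit_stratum(
    series_group: Sequence[MonthSeries],
    q_floor: float = DEFAULT_Q_FLOOR,
    B: int = DEFAULT_BOOTSTRAP_B,
    seed: int | None = None,
) -> MarFit | None:
    """Fit one taxon x region x month stratum end to end.

    Convenience wrapper: extract differences, fit the MLE, bootstrap the
    CIs. Returns None (logged) when the stratum carries no differences.
    """
    diffs = extract_differences(series_group)
    first = series_group[0]
    if not diffs:
        logger.info(
            "stratum taxon=%s region=%s month=%d has no usable differences; "
            "not modeled", first.taxon, first.region, first.month,
        )
        return None
    fit = fit_drift_variance(
        diffs, q_floor=q_floor,
        taxon=first.taxon, region=first.region, month=first.month,
    )
    return bootstrap_ci(fit, diffs, B=B, seed=seed, q_floor=q_floor)
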