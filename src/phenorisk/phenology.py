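"""High-abundance windows and monthly risk profiles.

A taxon's high-abundance window in a region is the set of calendar months
that together hold at least a target share (default 80%) of its mean
annual catch, months being added in descending order of monthly mean CPUE;
single-month gaps between selected months are then filled so the window is
uninterrupted. The calendar is treated circularly, so a December-January
window is contiguous.

Monthly risk profiles pair each modeled month's baseline decline risk with
that month's mean catch; their association is summarised by a Pearson
correlation across months.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .marfit import DEFAULT_Q_FLOOR, MarFit
from .risk import RiskQuery, scenario_risks

__all__ = [
    "AbundanceWindow",
    "MonthlyProfile",
    "monthly_mean_catch",
    "high_abundance_window",
    "monthly_risk_profile",
    "risk_abundance_correlation",
    "DEFAULT_COVERAGE_TARGET",
    "DEFAULT_MAX_GAP",
]

logger = logging.getLogger(__name__)

#: Share of mean annual catch a window must cover.
DEFAULT_COVERAGE_TARGET = 0.80
#: Longest run of unselected months filled to keep a window uninterrupted.
DEFAULT_MAX_GAP = 1


@dataclass(frozen=True)
class AbundanceWindow:
    """Months holding the bulk of a taxon's mean annual catch in a region.

    ``months`` is ordered along the circular calendar (a Dec-Jan window is
    ``(12, 1)``); ``coverage`` is the share of total mean catch inside the
    final (gap-filled) window; ``contiguous`` is False when gaps longer
    than ``max_gap`` remained after selection.
    """

    taxon: str
    region: str
    months: tuple
    coverage: float
    contiguous: bool = True

    def __post_init__(self) -> None:
        if not self.months:
            raise ValueError("window months must be nonempty")
        if not 0.0 < self.coverage <= 1.0:
            raise ValueError("coverage must lie in (0, 1]")

    def label(self) -> str:
        """Compact label, e.g. ``"4-6"`` or ``"12-1"`` (wrapping)."""
        if self.contiguous and len(self.months) > 1:
            return f"{self.months[0]}-{self.months[-1]}"
        return ",".join(str(m) for m in self.months)


@dataclass
class MonthlyProfile:
    """Per-calendar-month mean catch and baseline risk for a taxon x region."""

    taxon: str
    region: str
    mean_catch: np.ndarray  # 12 values, untransformed CPUE scale
    risk: np.ndarray  # 12 values, NaN where the stratum is not modeled
    observed: np.ndarray = field(
        default_factory=lambda: np.ones(12, dtype=bool)
    )

    def __post_init__(self) -> None:
        self.mean_catch = np.asarray(self.mean_catch, dtype=float)
        self.risk = np.asarray(self.risk, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.mean_catch.shape != (12,) or self.risk.shape != (12,):
            raise ValueError("mean_catch and risk must hold 12 monthly values")
        if np.any(self.mean_catch < 0):
            raise ValueError("mean_catch must be non-negative")
        present = ~np.isnan(self.risk)
        if np.any((self.risk[present] < 0) | (self.risk[present] > 1)):
            raise ValueError("risk values must lie in [0, 1]")


def monthly_mean_catch(series: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Mean CPUE per calendar month for one taxon x region.

    ``series`` is a tidy frame (year, month, value, observed) for the
    taxon's stations in the region, values on the ln(CPUE+1) scale; means
    are taken on the back-transformed CPUE scale across years and
    stations. Returns ``(means, observed_flags)``; months never surveyed
    get mean 0 and flag False.
    """
    means = np.zeros(12)
    flags = np.zeros(12, dtype=bool)
    obs = series[series["observed"]]
    by_month = obs.groupby("month")["value"].apply(
        lambda v: float(np.mean(np.expm1(v)))
    )
    for month, m in by_month.items():
        means[int(month) - 1] = m
        flags[int(month) - 1] = True
    return means, flags


def _circular_runs(unselected: Sequence[int]) -> list[list[int]]:
    """Maximal runs of consecutive months on the circular calendar."""
    if not unselected:
        return []
    sel = set(range(1, 13)) - set(unselected)
    if not sel:
        return [list(unselected)]
    runs, run = [], []
    # walk the calendar starting just after a selected month so runs do not wrap
    start = (max(sel) % 12) + 1
    order = [(start + i - 1) % 12 + 1 for i in range(12)]
    for m in order:
        if m in sel:
            if run:
                runs.append(run)
                run = []
        else:
            run.append(m)
    if run:
        runs.append(run)
    return runs


def high_abundance_window(
    means: np.ndarray,
    taxon: str = "",
    region: str = "",
    coverage_target: float = DEFAULT_COVERAGE_TARGET,
    max_gap: int = DEFAULT_MAX_GAP,
) -> AbundanceWindow:
    """Detect the high-abundance window from 12 monthly mean catches.

    Months are added in descending order of mean (ties broken toward the
    earlier calendar month) until their cumulative share of the annual
    total reaches ``coverage_target``; runs of at most ``max_gap``
    unselected months lying between selected months are then filled, and
    the coverage is recomputed on the final set. Contiguity is evaluated
    on the circular calendar.
    """
    means = np.asarray(means, dtype=float)
    if means.shape != (12,):
        raise ValueError("means must hold 12 monthly values")
    total = means.sum()
    if total <= 0:
        raise ValueError("all-zero monthly means: no window exists")

    order = sorted(range(1, 13), key=lambda m: (-means[m - 1], m))
    selected: set[int] = set()
    cum = 0.0
    for m in order:
        selected.add(m)
        cum += means[m - 1]
        if cum / total >= coverage_target:
            break

    runs = _circular_runs([m for m in range(1, 13) if m not in selected])
    gap_runs = [r for r in runs if len(r) <= max_gap] if len(selected) < 12 else []
    for r in gap_runs:
        selected.update(r)
    long_runs = [r for r in runs if len(r) > max_gap]
    contiguous = len(long_runs) <= 1  # one long unselected arc = contiguous window

    coverage = min(1.0, float(means[[m - 1 for m in sorted(selected)]].sum() / total))
    months = _order_circular(selected)
    if not contiguous:
        logger.info(
            "window for taxon=%s region=%s is non-contiguous after %d-month "
            "gap fill: months %s", taxon, region, max_gap, months,
        )
    return AbundanceWindow(
        taxon=taxon,
        region=region,
        months=months,
        coverage=coverage,
        contiguous=contiguous,
    )


def _order_circular(selected: set[int]) -> tuple:
    """Order months along the calendar, starting after the longest gap."""
    if len(selected) == 12:
        return tuple(range(1, 13))
    runs = _circular_runs([m for m in range(1, 13) if m not in selected])
    longest = max(runs, key=len)
    start = (longest[-1] % 12) + 1
    order = [(start + i - 1) % 12 + 1 for i in range(12)]
    return tuple(m for m in order if m in selected)


def monthly_risk_profile(
    fits: Mapping[int, MarFit],
    query: RiskQuery,
    mean_catch: np.ndarray | None = None,
    observed: np.ndarray | None = None,
    taxon: str = "",
    region: str = "",
    q_floor: float = DEFAULT_Q_FLOOR,
) -> MonthlyProfile:
    """Baseline risk per modeled month; unmodeled months flagged absent (NaN)."""
    if not fits:
        raise ValueError("at least one monthly fit required")
    risk = np.full(12, np.nan)
    for month, fit in fits.items():
        est = scenario_risks(fit, query, q_floor=q_floor)
        risk[month - 1] = est.p_baseline
    if mean_catch is None:
        mean_catch = np.zeros(12)
    if observed is None:
        observed = np.ones(12, dtype=bool)
    any_fit = next(iter(fits.values()))
    return MonthlyProfile(
        taxon=taxon or any_fit.taxon,
        region=region or any_fit.region,
        mean_catch=mean_catch,
        risk=risk,
        observed=observed,
    )


def risk_abundance_correlation(
    profile: MonthlyProfile,
) -> tuple[float, float]:
    """Pearson correlation of monthly risk with monthly mean catch.

    Pairs (risk_m, mean_catch_m) over months where both are present;
    returns ``(r, p)`` with p from the t transform on n-2 degrees of
    freedom. Requires >= 3 complete months; zero variance in either
    vector yields ``(nan, nan)`` (undefined correlation, logged).
    """
    mask = ~np.isnan(profile.risk) & profile.observed
    if mask.sum() < 3:
        raise ValueError("need >= 3 months with both risk and mean catch")
    x = profile.risk[mask]
    y = profile.mean_catch[mask]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning(
            "risk-abundance correlation undefined for taxon=%s region=%s: "
            "zero variance", profile.taxon, profile.region,
        )
        return (math.nan, math.nan)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
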