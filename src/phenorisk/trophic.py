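"""Predator-prey risk pairing, projection and divergence.

Each fish predator in a region is paired with every retained co-occurring
zooplankton taxon (no diet filtering — any commonly co-occurring
zooplankter is treated as potential prey). Prey risk is averaged over the
predator's high-abundance window; both trajectories are projected over
integer horizons (default 1-10 years).

Divergence is quantified on logit-transformed risk with an
ordinary-least-squares model

    logit(p) ~ time + group + time:group        (per predator-prey pair)

whose interaction coefficient is the difference in logit-risk slopes over
time (fish minus zooplankton): a positive value means predator risk
accumulates faster than prey risk. Uncertainty is the worst-minus-best
scenario width per horizon and group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .marfit import DEFAULT_Q_FLOOR, MarFit
from .phenology import AbundanceWindow
from .risk import DECLINE_90_THRESHOLD, RiskQuery, scenario_risks

__all__ = [
    "PredatorPreyPair",
    "DivergenceSummary",
    "prey_window_risk",
    "build_pairs",
    "logit",
    "divergence_model",
    "uncertainty_width",
    "DEFAULT_LOGIT_EPS",
    "DEFAULT_HORIZONS",
]

logger = logging.getLogger(__name__)

#: Clamp keeping logit finite at risks of exactly 0 or 1.
DEFAULT_LOGIT_EPS = 1e-6
#: Projection horizons in years.
DEFAULT_HORIZONS = tuple(range(1, 11))


@dataclass
class PredatorPreyPair:
    """One fish predator and its co-occurring prey assemblage in a region.

    Risk arrays are aligned with ``horizons``; ``prey_*`` entries are the
    per-horizon mean over prey taxa of their window-averaged risks.
    """

    region: str
    predator: str
    prey_set: tuple
    window: AbundanceWindow
    horizons: tuple
    predator_baseline: np.ndarray
    predator_best: np.ndarray
    predator_worst: np.ndarray
    prey_baseline: np.ndarray
    prey_best: np.ndarray
    prey_worst: np.ndarray
    prey_table: pd.DataFrame | None = None  # per (prey, horizon) baseline risk

    def __post_init__(self) -> None:
        if not self.prey_set:
            raise ValueError("prey_set must be nonempty")
        n = len(self.horizons)
        for name in (
            "predator_baseline", "predator_best", "predator_worst",
            "prey_baseline", "prey_best", "prey_worst",
        ):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must align with horizons")
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{name} must lie in [0, 1]")
            setattr(self, name, arr)


@dataclass
class DivergenceSummary:
    """Per-horizon gap and slope divergence for one (region, predator)."""

    region: str
    predator: str
    horizons: tuple
    gap: np.ndarray  # predator risk - prey mean risk, per horizon
    slope_gap: float  # fish-minus-zooplankton logit-risk slope over time
    uncertainty_fish: np.ndarray  # worst - best width, per horizon
    uncertainty_zoop: np.ndarray


def logit(p, eps: float = DEFAULT_LOGIT_EPS):
    """ln(p/(1-p)) with p clamped to [eps, 1-eps]; accepts arrays."""
    p = np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)
    out = np.log(p / (1.0 - p))
    return float(out) if out.ndim == 0 else out


def prey_window_risk(
    prey_fits: Mapping[str, Mapping[int, MarFit]],
    window: AbundanceWindow,
    query: RiskQuery,
    q_floor: float = DEFAULT_Q_FLOOR,
) -> dict:
    """Window-mean baseline risk per prey taxon.

    ``prey_fits`` maps taxon -> (month -> fit). For each taxon the
    arithmetic mean of its monthly baseline risks over the window months
    it is modeled in; taxa with no modeled window month are excluded with
    a log entry. Returns taxon -> (mean_baseline, mean_best, mean_worst).
    """
    out = {}
    for taxon, fits in prey_fits.items():
        months = [m for m in window.months if m in fits]
        if not months:
            logger.info(
                "prey taxon=%s has no modeled month inside window %s; excluded",
                taxon, window.months,
            )
            continue
        ests = [scenario_risks(fits[m], query, q_floor=q_floor) for m in months]
        out[taxon] = (
            float(np.mean([e.p_baseline for e in ests])),
            float(np.mean([e.p_best for e in ests])),
            float(np.mean([e.p_worst for e in ests])),
        )
    if not out:
        raise ValueError(
            f"no prey taxon has a modeled month inside window {window.months}"
        )
    return out


def build_pairs(
    fish_fits: Mapping[tuple, Mapping[int, MarFit]],
    fish_windows: Mapping[tuple, AbundanceWindow],
    zoop_fits: Mapping[tuple, Mapping[int, MarFit]],
    a: float = DECLINE_90_THRESHOLD,
    horizons: Sequence[int] = DEFAULT_HORIZONS,
    q_floor: float = DEFAULT_Q_FLOOR,
) -> list[PredatorPreyPair]:
    """Assemble one predator-prey pair per (region, fish predator).

    ``fish_fits`` and ``zoop_fits`` map (region, taxon) -> (month -> fit);
    ``fish_windows`` maps (region, taxon) -> window. Prey are all retained
    zooplankton taxa of the region (no diet filtering); predator risk is
    the mean over its window months of its own monthly risks. Predators
    with no window or no prey are skipped with a warning.
    """
    horizons = tuple(horizons)
    zoop_by_region: dict = {}
    for (region, taxon), fits in zoop_fits.items():
        zoop_by_region.setdefault(region, {})[taxon] = fits

    pairs: list[PredatorPreyPair] = []
    for (region, predator), fits in sorted(fish_fits.items()):
        window = fish_windows.get((region, predator))
        if window is None:
            logger.warning(
                "predator %s in region %s has no abundance window; skipped",
                predator, region,
            )
            continue
        prey = zoop_by_region.get(region)
        if not prey:
            logger.warning(
                "predator %s in region %s has no co-occurring zooplankton; "
                "skipped", predator, region,
            )
            continue
        pb, pbe, pw = [], [], []
        prey_b, prey_be, prey_w = [], [], []
        prey_rows = []
        prey_names: tuple = ()
        for T in horizons:
            query = RiskQuery(a=a, T=T)
            # predator risk during its own window
            own = prey_window_risk({predator: fits}, window, query, q_floor)[predator]
            pb.append(own[0]); pbe.append(own[1]); pw.append(own[2])
            pr = prey_window_risk(prey, window, query, q_floor)
            prey_names = tuple(sorted(pr))
            prey_b.append(np.mean([pr[t][0] for t in prey_names]))
            prey_be.append(np.mean([pr[t][1] for t in prey_names]))
            prey_w.append(np.mean([pr[t][2] for t in prey_names]))
            prey_rows.extend(
                {"prey": t, "horizon": T, "risk": pr[t][0]} for t in prey_names
            )
        pairs.append(
            PredatorPreyPair(
                region=region,
                predator=predator,
                prey_set=prey_names,
                window=window,
                horizons=horizons,
                predator_baseline=np.array(pb),
                predator_best=np.array(pbe),
                predator_worst=np.array(pw),
                prey_baseline=np.array(prey_b),
                prey_best=np.array(prey_be),
                prey_worst=np.array(prey_w),
                prey_table=pd.DataFrame(prey_rows),
            )
        )
    return pairs


def _interaction_slope(t: np.ndarray, g: np.ndarray, y: np.ndarray,
                       extra: np.ndarray | None = None) -> float:
    """OLS coefficient of the time x group interaction."""
    cols = [np.ones_like(t), t, g, t * g]
    if extra is not None:
        cols.extend(extra.T if extra.ndim > 1 else [extra])
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        missing = "fish" if not g.any() else ("zooplankton" if g.all() else "time")
        raise ValueError(
            f"rank-deficient divergence design: level {missing!r} has no variation"
        )
    res = sm.OLS(y, X).fit()
    return float(res.params[3])


def uncertainty_width(estimate) -> float:
    """Worst-minus-best scenario width of a risk estimate."""
    return float(estimate.p_worst - estimate.p_best)


def divergence_model(
    pairs: Sequence[PredatorPreyPair],
    eps: float = DEFAULT_LOGIT_EPS,
) -> tuple[list[DivergenceSummary], pd.DataFrame]:
    """Quantify predator-prey risk divergence per pair and per region.

    Per pair: the per-horizon gap (predator minus prey-mean baseline
    risk), the fish-minus-zooplankton logit-risk slope over time (the OLS
    time x group interaction coefficient), and per-group worst-minus-best
    uncertainty widths. The community table aggregates within regions:
    mean gap per horizon equals the mean of the constituent pair gaps, and
    the community slope gap comes from the pooled per-region OLS.

    Requires >= 2 horizons; a design in which one group is absent fails
    naming the missing level.
    """
    if not pairs:
        raise ValueError("no predator-prey pairs")
    summaries: list[DivergenceSummary] = []
    rows = []
    for pair in pairs:
        if len(pair.horizons) < 2:
            raise ValueError("divergence needs >= 2 horizons")
        t = np.asarray(pair.horizons, dtype=float)
        y = np.concatenate([logit(pair.predator_baseline, eps),
                            logit(pair.prey_baseline, eps)])
        tt = np.concatenate([t, t])
        g = np.concatenate([np.ones_like(t), np.zeros_like(t)])
        slope_gap = _interaction_slope(tt, g, y)
        summaries.append(
            DivergenceSummary(
                region=pair.region,
                predator=pair.predator,
                horizons=pair.horizons,
                gap=pair.predator_baseline - pair.prey_baseline,
                slope_gap=slope_gap,
                uncertainty_fish=pair.predator_worst - pair.predator_best,
                uncertainty_zoop=pair.prey_worst - pair.prey_best,
            )
        )
        rows.append(pd.DataFrame({
            "region": pair.region,
            "predator": pair.predator,
            "horizon": pair.horizons,
            "gap": summaries[-1].gap,
            "uncertainty_fish": summaries[-1].uncertainty_fish,
            "uncertainty_zoop": summaries[-1].uncertainty_zoop,
            "slope_gap": slope_gap,
        }))
    pair_table = pd.concat(rows, ignore_index=True)

    community = []
    for region, group in pair_table.groupby("region"):
        region_pairs = [p for p in pairs if p.region == region]
        t = np.concatenate(
            [np.asarray(p.horizons, float) for p in region_pairs] * 2
        )
        y = np.concatenate(
            [logit(p.predator_baseline, eps) for p in region_pairs]
            + [logit(p.prey_baseline, eps) for p in region_pairs]
        )
        n = sum(len(p.horizons) for p in region_pairs)
        g = np.concatenate([np.ones(n), np.zeros(n)])
        slope = _interaction_slope(t, g, y)
        mean_gap = group.groupby("horizon")["gap"].mean()
        community.append(pd.DataFrame({
            "region": region,
            "horizon": mean_gap.index,
            "mean_gap": mean_gap.to_numpy(),
            "mean_uncertainty_fish":
                group.groupby("horizon")["uncertainty_fish"].mean().to_numpy(),
            "mean_uncertainty_zoop":
                group.groupby("horizon")["uncertainty_zoop"].mean().to_numpy(),
            "slope_gap": slope,
        }))
    return summaries, pd.concat(community, ignore_index=True)
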