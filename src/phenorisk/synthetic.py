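"""Synthetic monitoring-survey generator.

Emulates a long-term monthly trawl/net survey of an estuarine community:
each taxon's yearly log-abundance follows a random walk with drift (the
same stochastic model the downstream viability analysis assumes), the
yearly abundance is spread across calendar months according to a seasonal
phenology profile, counts are thinned by imperfect detection and scaled by
per-tow sampling effort, and whole station-month surveys are occasionally
skipped.

All randomness flows from one integer seed through a documented
``numpy.random.SeedSequence`` spawning scheme, so identical specifications
yield bit-identical survey tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaxonSpec",
    "SurveyDesign",
    "generate_random_walk",
    "generate_survey_data",
    "write_survey_csv",
    "write_truth_csv",
    "SURVEY_COLUMNS",
]

#: Column order of the standard survey CSV.
SURVEY_COLUMNS = ["date", "station", "region", "taxon", "group", "count", "effort"]

VALID_GROUPS = ("fish", "zooplankton")

#: Shape of the gamma distribution effort is drawn from (mean = effort_mean,
#: coefficient of variation 20%) — effort varies tow to tow but is never zero.
_EFFORT_GAMMA_SHAPE = 25.0


@dataclass(frozen=True)
class TaxonSpec:
    """Generative parameters for one simulated taxon.

    Parameters
    ----------
    taxon_id
        Label used in the survey table.
    group
        ``"fish"`` or ``"zooplankton"``.
    drift
        Per-year mean change of log-abundance (the true drift U).
    proc_var
        Per-year variance of the log-abundance increment (the true
        process variance Q); environmental stochasticity.
    peak_months
        Calendar months (1-12) holding the seasonal abundance peak.
    peak_concentration
        Fraction of the annual abundance placed in the peak months.
    detection_prob
        Probability that a present taxon yields a nonzero count in a tow
        (zero inflation via Bernoulli thinning).
    base_log_abundance
        Log-abundance at the first simulated year (x0).
    """

    taxon_id: str
    group: str
    drift: float
    proc_var: float
    peak_months: frozenset = frozenset({4, 5, 6})
    peak_concentration: float = 0.8
    detection_prob: float = 1.0
    base_log_abundance: float = 6.0

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValueError(f"group must be one of {VALID_GROUPS}, got {self.group!r}")
        if self.proc_var < 0:
            raise ValueError(f"proc_var must be >= 0, got {self.proc_var}")
        if not 0.0 <= self.peak_concentration <= 1.0:
            raise ValueError("peak_concentration must lie in [0, 1]")
        if not 0.0 < self.detection_prob <= 1.0:
            raise ValueError("detection_prob must lie in (0, 1]")
        months = frozenset(int(m) for m in self.peak_months)
        if not months:
            raise ValueError("peak_months must be nonempty")
        if not months <= set(range(1, 13)):
            raise ValueError("peak_months must be calendar months 1-12")
        object.__setattr__(self, "peak_months", months)

    def month_weights(self) -> np.ndarray:
        """Fraction of annual abundance in each calendar month (sums to 1)."""
        w = np.zeros(12)
        peak = sorted(self.peak_months)
        off = [m for m in range(1, 13) if m not in self.peak_months]
        w[[m - 1 for m in peak]] = self.peak_concentration / len(peak)
        if off:
            w[[m - 1 for m in off]] = (1.0 - self.peak_concentration) / len(off)
        else:  # every month is a peak month: spread the remainder too
            w[[m - 1 for m in peak]] += (1.0 - self.peak_concentration) / len(peak)
        return w


@dataclass(frozen=True)
class SurveyDesign:
    """Sampling layout of the simulated monitoring programme."""

    years: tuple
    regions: tuple
    stations_per_region: int
    missing_rate: float = 0.0
    effort_mean: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        y0, y1 = int(self.years[0]), int(self.years[1])
        if y1 - y0 + 1 < 2:
            raise ValueError("survey must span at least 2 years")
        object.__setattr__(self, "years", (y0, y1))
        object.__setattr__(self, "regions", tuple(self.regions))
        if not self.regions:
            raise ValueError("at least one region required")
        if self.stations_per_region < 1:
            raise ValueError("at least one station per region required")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.effort_mean <= 0:
            raise ValueError("effort_mean must be positive")

    @property
    def n_years(self) -> int:
        return self.years[1] - self.years[0] + 1

    def station_labels(self) -> list:
        """(station, region) pairs, stations named ``<region>-S<j>``."""
        return [
            (f"{region}-S{j + 1}", region)
            for region in self.regions
            for j in range(self.stations_per_region)
        ]


def generate_random_walk(
    U: float,
    Q: float,
    n_years: int,
    x0: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate a yearly random walk with drift on the log scale.

    x_t = x_{t-1} + U + w_t with w_t ~ N(0, Q); x_1 = x0.

    Exactly one of ``seed`` / ``rng`` supplies the randomness (with Q = 0
    neither is needed).
    """
    if Q < 0:
        raise ValueError(f"process variance Q must be >= 0, got {Q}")
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    increments = np.full(n_years - 1, float(U))
    if Q > 0 and n_years > 1:
        if rng is None:
            rng = np.random.default_rng(seed)
        increments = increments + rng.normal(0.0, np.sqrt(Q), size=n_years - 1)
    return np.concatenate([[float(x0)], float(x0) + np.cumsum(increments)])


def generate_survey_data(
    taxa: Sequence[TaxonSpec], design: SurveyDesign
) -> pd.DataFrame:
    """Simulate the full survey table.

    One row per (station, year, month, taxon), minus skipped surveys.
    Counts are Poisson draws around ``exp(latent) * month_weight * effort``,
    thinned by ``detection_prob``; a skipped survey removes the rows of all
    taxa at that station-month.

    Stream-splitting scheme: the design seed spawns one child stream for
    the survey layout (missingness, then effort) and one child per taxon
    (station walks, then detection, then counts), in taxon list order.

    Returns a DataFrame with :data:`SURVEY_COLUMNS`.
    """
    if not taxa:
        raise ValueError("at least one TaxonSpec required")
    ids = [t.taxon_id for t in taxa]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate taxon_id in taxa")

    root = np.random.SeedSequence(design.seed)
    layout_ss, *taxa_ss = root.spawn(1 + len(taxa))
    layout_rng = np.random.default_rng(layout_ss)

    stations = design.station_labels()
    n_st, n_y = len(stations), design.n_years
    years = np.arange(design.years[0], design.years[1] + 1)

    # survey layout shared by all taxa: which station-months happen, at what effort
    surveyed = layout_rng.random((n_st, n_y, 12)) >= design.missing_rate
    effort = layout_rng.gamma(
        _EFFORT_GAMMA_SHAPE, design.effort_mean / _EFFORT_GAMMA_SHAPE, (n_st, n_y, 12)
    )

    frames = []
    for spec, ss in zip(taxa, taxa_ss):
        t_rng = np.random.default_rng(ss)
        walks = np.empty((n_st, n_y))
        for s in range(n_st):
            walks[s] = generate_random_walk(
                spec.drift, spec.proc_var, n_y, spec.base_log_abundance, rng=t_rng
            )
        lam = np.exp(walks)[:, :, None] * spec.month_weights()[None, None, :] * effort
        present = t_rng.random((n_st, n_y, 12)) < spec.detection_prob
        counts = t_rng.poisson(lam) * present

        st_idx, y_idx, m_idx = np.nonzero(surveyed)
        frames.append(
            pd.DataFrame(
                {
                    "date": [
                        f"{y:04d}-{m + 1:02d}-01"
                        for y, m in zip(years[y_idx], m_idx)
                    ],
                    "station": [stations[i][0] for i in st_idx],
                    "region": [stations[i][1] for i in st_idx],
                    "taxon": spec.taxon_id,
                    "group": spec.group,
                    "count": counts[st_idx, y_idx, m_idx],
                    "effort": effort[st_idx, y_idx, m_idx],
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["station", "date", "taxon"], kind="stable")
    return out.reset_index(drop=True)[SURVEY_COLUMNS]


def write_survey_csv(records: pd.DataFrame, path: str | Path) -> None:
    """Write the standard survey CSV (effort at full float precision)."""
    records.to_csv(path, index=False)


def write_truth_csv(taxa: Sequence[TaxonSpec], path: str | Path) -> None:
    """Write the generator ground truth used by recovery tests."""
    rows = [
        {
            "taxon": t.taxon_id,
            "group": t.group,
            "U_true": t.drift,
            "Q_true": t.proc_var,
            "peak_months": "-".join(str(m) for m in sorted(t.peak_months)),
            "peak_concentration": t.peak_concentration,
            "detection_prob": t.detection_prob,
            "base_log_abundance": t.base_log_abundance,
        }
        for t in taxa
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def taxon_to_dict(spec: TaxonSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["peak_months"] = sorted(spec.peak_months)
    return d


def taxon_from_dict(d: dict) -> TaxonSpec:
    d = dict(d)
    d["peak_months"] = frozenset(int(m) for m in d["peak_months"])
    return TaxonSpec(**d)
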