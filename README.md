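# phenorisk

Phenology-informed population viability analysis (PVA) for monitored
predator–prey communities.

Long-term biomonitoring programmes (monthly trawl or net surveys at fixed
stations) produce count time series for many taxa at once. `phenorisk`
turns such data into **critical decline risk**: the probability that a
population falls a fixed fraction (by default 90%) below its current
level within a time horizon — estimated separately for *each calendar
month* of the year, so that risk during a species' seasonal
high-abundance window can be compared with its "shoulder" months, and a
fish predator's risk trajectory can be compared with that of its
zooplankton prey. It is aimed at quantitative ecologists and conservation
analysts working with survey data of age-0 fishes, zooplankton, or any
community sampled on a monthly grid.

## The model

Log-transformed catch per unit effort, `X_t = ln(CPUE + 1)`, for one
taxon in one region and one calendar month is modeled as a
station-replicated random walk with drift:

```
X_t = X_{t-1} + U + W_t,     W_t ~ N(0, Q)
```

with a single drift `U` (per-year trend) and a single process-error
variance `Q` shared across the region's stations (increments independent
between stations). Gaps of `k` missing years contribute differences
distributed `N(kU, kQ)`, so the maximum-likelihood estimates have closed
form: `U_hat = Σδ/Σk` and `Q_hat = mean((δ − kU_hat)²/k)`. 95% confidence
intervals come from a parametric bootstrap over the identical observation
pattern.

Treating log-abundance as Brownian motion with drift `U` and
infinitesimal variance `Q`, the probability of an `a`-sized decline
within `T` years (first passage of a lower barrier, the inverse-Gaussian
tail) is

```
P_e = Φ(μ − V) + exp(2μV) · Φ(−μ − V),
μ = −UT/√(QT),   V = a/√(QT),   a = ln 10  (90% decline)
```

with Φ the standard normal CDF. Risk is evaluated under three scenarios:
*baseline* `(U_hat, Q_hat)`, *best case* `(U_hi, Q_lo)` and *worst case*
`(U_lo, Q_hi)`; the worst-minus-best width is the risk uncertainty.

Around that core the pipeline provides: data screening (minimum nonzero
detections per station series — 50 for fish, 234 for zooplankton — and
≥30% presence across surveyed years per month stratum), high-abundance
window detection (the circularly contiguous months holding ≥80% of mean
annual catch, single-month gaps filled), predator–prey pairing of each
fish with all co-occurring retained zooplankton, 1–10 year projections,
and an OLS model of logit-transformed risk on time × trophic group whose
interaction coefficient measures how fast predator risk diverges from
prey risk. A seeded synthetic-survey generator with the same stochastic
structure (random-walk log-abundance, seasonal phenology, zero-inflated
counts, effort scaling, skipped surveys) makes every stage testable
without real agency data.

## Worked example

```python
import math
from phenorisk import RiskQuery, quasi_extinction_probability, MarFit, scenario_risks

p = quasi_extinction_probability(U=-0.1, Q=0.04, query=RiskQuery(a=math.log(10), T=10))
print(f"10-year 90%-decline risk: {p:.4f}")

fit = MarFit(taxon="smelt_like", region="Suisun", month=3,
             U_hat=-0.12, Q_hat=0.05, U_lo=-0.20, U_hi=-0.04,
             Q_lo=0.03, Q_hi=0.09)
est = scenario_risks(fit, RiskQuery(a=math.log(10), T=10))
print(f"baseline={est.p_baseline:.3f} best={est.p_best:.3f} worst={est.p_worst:.3f}")
```

prints

```
10-year 90%-decline risk: 0.0286
baseline=0.082 best=0.000 worst=0.455
```

A population declining 0.1 per year on the log scale with modest process
variance has a 2.9% chance of crossing the 90%-decline barrier within a
decade; for the fitted stratum the bootstrap uncertainty spans
essentially safe (best case) to nearly even odds (worst case) — the 0.455
worst-case value is what a manager should plan against.

The full pipeline runs from a config file or the packaged demo community
(2 regions, 3 fish, 4 zooplankton, 29 years):

```
phenorisk all --demo --out demo_out --seed 1
```

writing `screened.csv`, `fits.csv`, `risks.csv`, `windows.csv`,
`profiles.csv`, `pairs.csv`, `divergence.csv` and `community.csv`, each
stamped with the configuration hash and seed (identical config + seed ⇒
byte-identical bundle). `examples/demo.yaml` is the same configuration in
editable form; stages can also be run one at a time
(`phenorisk simulate | screen | fit | risk | windows | trophic`).
In `divergence.csv`, `gap` is predator-minus-prey baseline risk per
horizon and `slope_gap` the fish-minus-zooplankton logit-risk slope — a
positive value means the predator accumulates decline risk faster than
its prey assemblage over the projection.

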