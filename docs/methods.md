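# Methods

## Model and assumptions

The analysis scale is `X_t = ln(CPUE + 1)`, where CPUE = count/effort and
multiple tows in the same station-month are averaged on the CPUE scale
before the transform (keeping CPUE additive in effort). The natural log
is used throughout: the diffusion formulas below conventionally live on
the natural-log scale.

Each taxon × region × calendar-month stratum is modeled as a
station-replicated random walk with drift,

    X_t = X_{t-1} + U + W_t,   W_t ~ N(0, Q),

with one drift `U` and one process variance `Q` per stratum. Assumptions:

- **No observation-error layer.** This is a deliberate modeling choice:
  a consistent process-error-only framework is applied to every taxon
  rather than an observation-error correction that converges for some
  strata and not others. Consequences: sampling noise (Poisson counting,
  imperfect detection) is absorbed into `Q`, so risk estimates are
  conservative upper bounds on process-driven risk, and comparisons
  between taxa/groups (the quantity of interest) are more robust than
  absolute risk magnitudes.
- **Equal, independent station increments.** The station covariance
  structure is diagonal with equal variance — the minimal assumption that
  keeps the likelihood separable; no interaction (B-matrix) or covariate
  terms are estimated.
- **Seasonal stationarity.** Splitting each year into 12 month-specific
  annual series assumes the within-year abundance pattern is stable
  across years; it also removes most serial autocorrelation from each
  fitted series.

### Estimation

Missing survey years are handled exactly rather than discarded: a
difference across `k` years is `N(kU, kQ)` under the model. The joint
Gaussian MLE on the pooled gap-differences has closed form,

    U_hat = Σδ_i / Σk_i            (independent of Q)
    Q_hat = mean((δ_i − k_i U_hat)² / k_i)

using the n-denominator (pure MLE, not n−1). `Q_hat` is floored at
`q_floor = 1e-10` (log² scale) so the risk formula stays defined for
noise-free series; floored fits are flagged degenerate. A fit needs ≥1
difference for `U` and ≥2 for a nondegenerate `Q`.

Confidence intervals are percentile 95% intervals from a parametric
bootstrap (default B = 1000): replicate difference sets are drawn as
`δ* ~ N(kU_hat, kQ_hat)` over the identical span pattern — exactly
equivalent to simulating series with the identical observation/missing
pattern and differencing — and refit with the closed form. This keeps the
bootstrap vectorizable and respects the data's missingness. A
200-replicate calibration study (29 years × 4 stations, U = −0.1,
Q = 0.05) is part of the acceptance script; coverage of the true drift
lands in the low-to-mid 90s.

### First-passage risk

For Brownian motion with drift `U` and infinitesimal variance `Q`, the
probability of falling `a` below the current level within `T` years is

    P_e = Φ(μ − V) + exp(2μV) Φ(−μ − V),
    μ = −UT/√(QT),   V = a/√(QT).

Algebraically this is Φ((−a−UT)/√(QT)) + exp(−2Ua/Q) Φ((−a+UT)/√(QT)),
the inverse-Gaussian first-passage tail. Limits used as exact tests:
`a = 0 → P = 1`; `T → ∞` gives `exp(−2Ua/Q)` for `U > 0` and 1 otherwise;
`Q → 0` gives the indicator of `−UT ≥ a`. The implementation is verified
against an independent Brownian-bridge Monte-Carlo simulation (below).

A 90% decline is encoded as `a = ln 10`, measured from the last observed
level on the transformed scale; the `+1` inside `ln(x+1)` is ignored for
barrier placement (the diffusion lives on the transformed scale and no
offset correction is attempted). The decline fraction is a config knob
(`a = −ln(1 − fraction)`).

Scenario risks: baseline `(U_hat, Q_hat)`, best case `(U_hi, Q_lo)`,
worst case `(U_lo, Q_hi)`; uncertainty = worst − best. The ordering
best ≤ baseline ≤ worst is *not* asserted anywhere: risk is not globally
monotone in `Q` (as `Q → 0` with `−UT > a` risk tends to 1), although the
ordering holds in the typical regime.

### Numerical hygiene

`exp(2μV)` overflows for small `Q`; the second term is evaluated as
`exp(2μV + logΦ(−μ−V))` via the normal log-CDF. Outputs are clamped to
[0, 1]. The implementation is finite and bounded over
|U| ≤ 2, Q ∈ [1e-10, 5], T ≤ 1e6 (property-tested). Logit transforms
clamp risk to [1e-6, 1−1e-6] since degenerate strata produce exact 0/1.

## Screening rules

- **Detection counts** (taxon × station, full monthly series, before
  month-splitting): retained iff nonzero-CPUE surveys ≥ 50 (fish) or
  ≥ 234 (zooplankton), inclusive. The threshold grain is per station.
- **Presence** (taxon × station × month): retained iff nonzero years /
  *surveyed* years ≥ 0.30 — the denominator is observed years, not the
  calendar span, so skipped surveys do not penalize a taxon.
- Both filters are idempotent and the CPUE computation is invariant to
  input row order.

## High-abundance windows

Months are selected in descending order of per-month mean CPUE (ties →
earlier calendar month) until the cumulative share of the annual total
reaches the coverage target (default 0.80); runs of ≤ `max_gap`
(default 1) unselected months lying between selected months are then
filled, and coverage is recomputed on the final set. The calendar is
circular, so December–January windows are contiguous and a Dec/Feb
selection has a fillable gap. Windows are defined on mean CPUE (the
analysis-scale operational "mean annual catch"). If longer gaps remain
the window is reported as the selected set and flagged non-contiguous.
Raising the coverage target never shrinks the window (property-tested).

## Trophic pairing and divergence

Every fish predator in a region is paired with *all* retained
co-occurring zooplankton taxa, equally weighted — no diet or selectivity
assumptions. Predator risk per horizon is the mean of its monthly
baseline risks over its own window months; prey risk is each prey's mean
over the window months it is modeled in, then averaged across prey.
Divergence is estimated by OLS on logit risk with time (years 1–10),
group (fish = 1) and their interaction; `slope_gap` is the interaction
coefficient (exactly antisymmetric under group-label swap). Effect
estimation is the goal; F-test significance machinery is intentionally
out of scope. Community summaries aggregate within regions, and the
community mean gap equals the mean of constituent pair gaps by
construction.

## Synthetic-data generator

The generator emulates the structure the analysis assumes: per station,
yearly latent log-abundance follows the random walk with the taxon's
true `(U, Q)`; `exp(latent)` is spread across months by a phenology
profile (`peak_concentration` mass on `peak_months`, the remainder
uniform elsewhere); counts are Poisson around abundance × month-weight ×
effort, thinned by a Bernoulli detection probability (the zero-inflation
mechanism); effort is gamma-distributed per survey (mean `effort_mean`,
CV 20%); whole station-month surveys are skipped with probability
`missing_rate`. All randomness flows from one seed through a
`SeedSequence` spawn: one stream for the survey layout (missingness,
effort), one per taxon (walks, detection, counts), in list order —
identical specs give bit-identical tables.

What it does **not** emulate: gear selectivity and mesh-size effects,
age/length structure, station geometry or spatial correlation between
stations, temporally correlated or drifting detectability, and
phenological shift across years. Passing tests therefore demonstrate
that the estimators recover the generating process when the model's
assumptions hold, not that those assumptions hold for any particular
real monitoring programme.

A consequence used deliberately in the recovery studies: at low
simulated abundance, Poisson counting noise contributes log-scale
increment variance of order `1/λ`, inflating fitted `Q` above the latent
process variance (exactly the observation-error absorption discussed
above). Studies that prescribe a target process variance therefore use
baseline log-abundances high enough (≈ 9–12) that counting noise is
negligible and the realized increment variance equals the prescribed
`Q`.

## Default parameters

| Parameter | Default | Meaning |
|---|---|---|
| `min_nonzero_fish` / `min_nonzero_zoop` | 50 / 234 | nonzero detections per station series |
| `min_presence` | 0.30 | nonzero fraction of surveyed years per month stratum |
| `coverage_target` / `max_gap` | 0.80 / 1 | window share of mean annual catch; fillable gap |
| `decline_fraction` | 0.90 | barrier `a = ln 10` on the log scale |
| `horizons` | 1…10 years | projection horizons |
| `bootstrap_B` | 1000 | parametric-bootstrap replicates |
| `q_floor` | 1e-10 | variance floor (log² scale) |
| `eps` | 1e-6 | logit clamp |

Demo community (packaged, seeded): 2 regions × 4 stations, monthly
1995–2023 (29 years), 5% skipped surveys, three fish (drifts −0.12,
−0.05, +0.05; process variances 0.03–0.20; spring/summer peaks) and four
zooplankters (drifts −0.02…+0.02, variances 0.05–0.15, broader peaks) —
spanning declining low-variance, stable, and volatile positive-growth
dynamics so every downstream comparison is exercised.

## Problem sizes and tolerances

The Monte-Carlo cross-check uses 1e5 Brownian-bridge-corrected paths per
grid point at step 0.05 yr (the bridge correction is exact in
distribution for Brownian motion at any step, so the step size only
trades Monte-Carlo cost, not bias) over U ∈ {−0.3, −0.1, 0, 0.1} ×
Q ∈ {0.01, 0.04, 0.25} × T ∈ {1, 5, 10} at `a = ln 10`, with agreement
required to 0.02. The CI calibration study uses 200 replicates with
B = 200 bootstrap draws (a deliberately scaled-down B; percentile
endpoints at B = 200 are noisy at the ±1% level, which the [0.90, 0.99]
coverage band accommodates). The divergence recovery study uses 100
seeded communities of 1 declining fish (U = −0.15) and 3 stationary prey
(U = 0), Q = 0.04, 29 years × 4 stations, with confidence intervals
collapsed to point estimates since the gap and slope statistics depend
only on baseline risk.

## Known limitations

- Absolute risk levels inherit the observation-error absorption into
  `Q`; cross-taxon and cross-group *comparisons* are the robust outputs.
- Month-splitting assumes stable within-year phenology; a taxon whose
  peak migrates across years will smear its windows.
- The bootstrap conditions on the observed missingness pattern; it does
  not model informative missingness.
- Percentile bootstrap intervals can slightly undercover for strongly
  skewed `Q` sampling distributions at small n.
- The divergence OLS treats per-horizon risks from one fitted stratum as
  independent observations; it is an effect-size summary, not an
  inferential test (standard errors would be badly miscalibrated, which
  is one reason significance testing is out of scope).
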