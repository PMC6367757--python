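# Methods

## Model

`bcrisk` projects the absolute (crude) risk of breast cancer under a
cause-specific competing-risk model. Two causes are modelled: breast
cancer, with cause-specific hazard r·h₁\*(t) for a woman whose composite
relative risk is r, and death from any other cause, with hazard h₂(t).
Both hazards are piecewise-constant on 5-year age bands; the default grid
has twelve bands covering ages 25–84 (half-open bands [start, start+5)).
The absolute risk over [a, a+τ) is

    P(a, τ, r) = ∫ r·h₁*(t) · exp(−∫ [r·h₁*(u) + h₂(u)] du) dt ,

the probability that breast cancer occurs first, before competing death
and before the horizon. Because the hazards are step functions the
integral has a closed form: for each sub-interval of length Δ with total
hazard λ = r·h₁\* + h₂, the event mass is S·(1 − e^(−λΔ)) split between the
causes in proportion r·h₁\* : h₂, with S the survival accumulated from a.
Sub-intervals with λ = 0 contribute nothing. This per-band recursion is
exact — no quadrature is involved — and the three outcome probabilities
(cancer first, competing death first, event-free survival) sum to one by
construction. The test suite checks the recursion against adaptive
quadrature of the integrand to 1e−10 on random schedules.

Assumptions worth stating: relative risks are constant in age and act
multiplicatively on the baseline hazard; rates are constant within each
5-year band (the standard convention for this family of models); the
projection never extends past the last band (age 85 on the default grid) —
queries beyond it are rejected rather than extrapolated.

## Risk factors and composite relative risk

Six factors are coded into ordered categories, code 0 being the reference
level with RR 1.0:

| factor | categories (code 0/1/2) | RR per category |
|---|---|---|
| number of abortions | 0 / 1–2 / ≥3 | 1 / 2.512 / 6.313 |
| age at first live birth | <25 / 25–29 / ≥30 | 1 / 1.895 / 3.589 |
| benign breast disease | no / yes | 1 / 4.255 |
| BMI (kg/m²) | <24 / 24–27.9 / ≥28 | 1 / 1.372 / 1.882 |
| family history of breast cancer | no / yes | 1 / 3.250 |
| life-satisfaction total | <13 / ≥13 | 1 / 2.424 |

BMI is weight/height²; the 24–27.9 class is implemented as the half-open
interval [24, 28) so that 27.95 codes 1 and 28.0 codes 2, consistent with
"≥28" for the top class. The life-satisfaction total sums six items each
scored 1 (very satisfied) to 5 (very unsatisfied), so it ranges 6–30; the
published dichotomy at ≥13 is applied to the raw sum. A woman's composite
RR is the product of her six category RRs — order-invariant, equal to 1.0
at the all-reference profile, and ≥1 under the default scheme since every
non-reference RR exceeds 1.

Estimating the RRs themselves (a conditional logistic regression on
matched case-control data) is out of scope: the scheme consumes them as
inputs, and alternative schemes can be supplied as CSV.

Nulliparous women have no published coding for age at first live birth.
The default assigns the reference level and logs a warning; the code is
configurable (`nulliparous_code`). This is deliberately conservative — it
can only understate such a woman's risk relative to any non-reference
choice — and flagged rather than silent.

## Baseline calibration

The baseline hazard h₁\*(t) — the breast-cancer hazard of a woman at the
reference level of every factor — is obtained by thinning the population
age-specific incidence rate: h₁\*(t) = incidence(t) × (1 − AR), where AR is
the population attributable risk of the six factors. AR is estimated by
Bruzzi's method from the distribution of cases over risk strata,
AR = 1 − Σ ρⱼ/rⱼ, with ρⱼ the proportion of cases in stratum j and rⱼ the
stratum's composite RR. Strata may be full factor cross-classifications
built from individual case profiles, or pre-aggregated (rⱼ, ρⱼ) pairs.
Because an AR belongs to the population whose case mixture produced it,
regions carry their own AR explicitly in the config — none is applied
silently.

## Regions and bundled data

A region YAML bundles the incidence table, the competing-mortality table,
the attributable risk, and optionally a pre-computed risk table for the
interpolation lookup. Rate CSVs use `age_start,age_end,rate_per_100k`;
rates are held internally per person-year.

The packaged region `synthetic_taixing` is built for testing and
demonstration. Its incidence and mortality tables are **synthetic**:
plausible age patterns for breast-cancer incidence (rising from ~6/100,000
person-years in the late twenties to a peak of ~62 around ages 50–54, then
declining) and for all-cause-minus-breast-cancer female mortality
(~40/100,000 rising to ~7,000 by the early eighties) in rural eastern
China circa 2015. They are not official registry figures, which are not
redistributed here; users with the real tables can point a region config
at them unchanged. The region's AR of 0.78 is the published population
value for the validation cohort. The packaged
`reference_risk_table.csv` is the published projected-risk grid (percent)
over initial ages {25, 30, 40, 50, 60, 70}, horizons {5, 10, 20, 30} and
RRs {1, 5, 10, 15, 20, 25}; the grid is ragged (age 25 has no 5-year row;
ages 60 and 70 stop where age + horizon would pass 85).

## Risk tables and interpolation

`build_risk_table` evaluates the exact engine on a grid; probabilities are
carried as proportions and rendered as percent (half-up, 2 decimals) only
at output. `interpolate_risk` reproduces the published lookup procedure:
linear interpolation along the RR axis only, between the two bracketing
grid RRs; age and horizon must match the grid exactly — off-grid queries
on those axes route to the exact engine, which is what the lookup merely
approximates. Extrapolation beyond the RR grid is off by default and, when
enabled, continues the last segment linearly and is logged.

## Validation statistics

Expected events are E = Σᵢ P(aᵢ, τᵢ, rᵢ) with τᵢ each woman's realized
follow-up (event, death or censoring time); a fixed-horizon mode is
available since the published choice is not stated. Competing deaths and
losses to follow-up contribute their model probability over observed time
and count as non-events in O. The E/O ratio carries a 95% CI from a
log-normal Poisson approximation on O, ratio × exp(∓1.96/√O) — a
documented choice of this package, adequate at the event counts involved
(tens of cases); it is undefined at O = 0.

The C-statistic is the probability that a randomly chosen case has a
higher predicted risk than a randomly chosen non-case, ties counted half.
It is computed from midranks (O(n log n)) and equals exhaustive
pair-counting exactly; the standard error is Hanley–McNeil with
Q₁ = c/(2−c), Q₂ = 2c²/(1+c), and the 95% CI is c ∓ 1.96·SE truncated to
[0, 1]. The crude incidence rate is cases/(persons × years) × 100,000.

## Synthetic cohorts

The simulator draws cohorts with exactly the structure the model assumes,
so every downstream statistic can be checked for self-consistency without
external data. Factor codes are sampled independently from marginal
category prevalences (the defaults are the non-case marginals of the
validation cohort: abortions 73.14/24.43/2.43%, first birth
74.97/23.88/1.15%, benign breast disease 0.35%, BMI 68.78/28.08/3.14%,
family history 0.68%, life-satisfaction ≥13 52.56%). Entry ages follow a
discretised normal (mean 46.8, SD 11.5 — the cohort's observed moments)
truncated to 25–77 so that entry plus the 7-year administrative horizon
stays inside the hazard grid. Event times use the latent cause-specific
construction: within each band slice the first-event time is exponential
with rate r·h₁\* + h₂ (inverse-CDF sampling of the truncated
exponential), and the cause is breast cancer with probability
r·h₁\*/(r·h₁\* + h₂). Administrative censoring is fixed at the horizon;
uniform random loss to follow-up is available (`loss_to_follow_up`,
default off — the real cohort lost 28.9%, but drop-out there was
administrative, not random, so it is not emulated by default).

What the simulator deliberately does not reproduce: correlation between
factors (only marginals are published; a correlated joint table can be
passed via `factor_prevalences` replacement at stratum level), secular
trends in rates, age-varying RRs, and informative drop-out. Passing
self-consistency tests therefore demonstrates internal correctness of the
estimators, not calibration of the model to any real population.

Two exact companions support parameter-recovery tests. `analytic_ar`
enumerates all 216 factor combinations: under a rare multiplicative
disease the case mixture is ρⱼ ∝ pⱼrⱼ and Bruzzi's estimand collapses to
AR = 1 − 1/E[r] (≈0.736 at the default prevalences — close to, but not
equal to, the published 0.78, which came from the real joint case
distribution). `sample_case_distribution` draws case profiles from the
model's exact case mixture, with stratum weight pⱼ × P̄ⱼ where P̄ⱼ averages
the stratum's absolute risk over the entry-age distribution; this is how
50,000 cases are generated for AR recovery without simulating the ~20
million women a raw cohort draw would need.

## Numerical choices and problem sizes

- Probabilities are proportions internally; percent rendering rounds
  half-up to 2 decimals (`percent_str`).
- λ = 0 band slices contribute zero event mass (no 0/0).
- Rate-table rows arriving out of order are sorted and logged; gaps,
  overlaps, mixed band widths and negative rates are rejected naming the
  offending band.
- The quadrature oracle in the tests integrates band-by-band with
  scipy's adaptive quadrature at epsabs 1e−14 and compares at 1e−10.
- Self-consistency problem sizes: 1,000 random schedules for the
  quadrature check; 50,000 sampled cases for AR recovery (tolerance
  ±0.02); 500 replicate cohorts of 13,176 women for E/O coverage, with
  the a-priori acceptance band 91–99% coverage of the nominal 95% CI;
  concordance cross-checked against exhaustive pair counting up to
  n = 200. These sizes make the Monte-Carlo error small relative to each
  tolerance while keeping the full suite around ten seconds.

## Known limitations

- The bundled rates being synthetic, "exact" projections from the bundled
  region approximate but do not reproduce published exact figures; the
  published risk-table grid is bundled verbatim, so the interpolation
  lookup does reproduce them.
- No lifetime-risk extrapolation beyond age 85, no time-varying RRs, no
  secular-trend adjustment.
- The E/O confidence interval method is an approximation chosen here; at
  very small O it is wide and at O = 0 undefined.
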