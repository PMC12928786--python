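# Methods

## Scope and model structure

`saltimpact` estimates the population health impact of category-specific
salt reformulation targets in two stages: a static microsimulation of
the effect of full target compliance on individual salt intake, and a
proportional multistate lifetable (PMSLT) that converts the resulting
mean systolic blood pressure (SBP) change into ischemic heart disease
(IHD) and ischemic stroke outcomes. Only these two diseases are
modelled; remission from both is fixed at zero. Diseases are treated as
independent end points: each runs its own 3-state process (no disease /
disease / dead-from-disease) and their mortality contributions are added
in the shared cohort lifetable.

## Diet stage

Baseline intake per person is Σ grams/day × salt-per-100 g / 100 over
matched, non-homemade records. Homemade and unmatched foods are excluded
from both baseline and scenario intakes — a conservative choice, since
any reformulation benefit in unmatched categories is not counted.

Target substitution is unconditional: a record whose salt content is
already below its per-100 g target is still set to the target. Out-of-
home targets are per serving; each reported record is treated as exactly
one serving regardless of grams (an optional `assumed_serving_g` /
`max_servings` switch relaxes this, off by default).

Under-reporting correction: factor = reference mean / survey-weighted
diary mean per sex × age-group stratum (19–34, 35–49, 50–64). Adults
outside 19–64 receive the nearest group's factor — minimal
extrapolation, logged. The factor multiplies baseline and scenario
intakes identically, so the *relative* reduction is invariant to it and
the absolute reduction scales with it; the `no_underreporting` variant
sets all factors to 1.

Confidence intervals for the stratified means and changes come from a
survey-weighted person-level bootstrap (persons resampled with
replacement, weights carried; percentile method; 2,000 replicates by
default, seeded). This choice respects the weighting and the skew of
intake distributions; it does not model any survey clustering or
stratification beyond the weights.

## Risk stage

ΔSBP = Δsalt × 5.80 / 5.88 mmHg: 5.80 mmHg (95% CI 2.45–9.15) per
100 mmol sodium, which is 2.30 g sodium or 5.88 g salt. The slope is
linear and sex-independent; the intake change is sex-specific.

SBP exposure is a normal distribution per age/sex, discretized into
1 mmHg bins (configurable) spanning ±6 SD, extended 10 mmHg downward so
baseline and shifted distributions share categories; prevalences are
renormalized to sum to 1. The relative risk is 1 at or below the
115 mmHg theoretical-minimum-risk level and log-linear in (SBP − 115)
above it, with age-band-specific slopes supplied as data (the exact
curvature of the BP–disease dose response is uncertain, so the slope
table is input, not code). PIF = (Σ p·RR − Σ p′·RR)/Σ p·RR is evaluated
on those categories; scenario incidence is I(1 − PIF), clamped to [0, 1]
with a warning. PIF values stabilise well below the bin width: across
bin widths 2 → 0.25 mmHg the change is < 1e-4.

## Lifetable engine

Conventions: annual cycles, single-year ages, closed cohorts (every
adult age/sex cohort alive at year 0), terminal age 110 with forced
death in the terminal year, no half-cycle correction. Rates convert to
probabilities as q = 1 − exp(−rate). Within a cycle, newly incident
cases are not exposed to case fatality until the next cycle. Competing
risks are resolved as independent exponentials: the total mortality
rate is other-cause + per-disease rates, and deaths are partitioned
across causes in proportion to their rates.

Other-cause mortality is all-cause minus the cause-specific rates in
the inputs and is identical in both runs; the scenario differs from
baseline only through incidence multipliers (1 − PIF). The intervention
ramps linearly over 4 years and incidence responds to the exposure of
5 years earlier, so the first incidence effect appears in year 6.
Incidence and case-fatality trends are annualized factors from a
log-linear fit to the 10 pre-baseline years of rate indices, applied in
years 1–10 and held constant afterwards, in both runs.

QALYs per year are person-years × max(baseline utility − Σ prevalent
decrements, 0); decrements for coexisting IHD and stroke are additive
(the combination rule is not identified by the data, so the simplest
was chosen and is isolated in one expression). Costs are prevalent
person-years × annual unit cost. QALYs and costs are discounted at
3.5% per year from year 0 (PV = Σ vₜ/(1+r)ᵗ); case and death counts
over the 20- and 30-year horizons are reported undiscounted, since
burden tables conventionally report counts while discounting applies to
valuation streams. Life expectancy is the population-weighted sum of
start-of-year survival; deltas are also reported in days (×365).

## Monte Carlo uncertainty

Families are chosen by support: lognormal for the salt–BP slope and RR
slopes, beta for utility decrements, gamma for cost multipliers,
zero-truncated normal for the intervention effect (per-sex salt change,
CI from the diet bootstrap), truncated normal for the baseline-utility
multiplier. Lognormal draws are quantile-matched to both CI bounds
(μ = midpoint of the log bounds); because the printed slope CI is
asymmetric about 5.80 on the log scale, the draw median is below 5.80 —
point estimates always come from the central-parameter run, so this
affects interval shape only, and the empirical 2.5/97.5 percentiles
reproduce the stated bounds. RR uncertainty enters as one standard-
normal quantile per disease applied jointly to all age bands (perfect
within-disease correlation; bands share an evidence base). Parameters
are drawn independently of each other — no cross-parameter correlation
structure is available — and each parameter has its own seed substream,
so perturbing one leaves the others' draws unchanged. The main analysis
specifies 10,000 iterations and sensitivity analyses 500; iterations
whose inputs fail validation are skipped and logged, with > 1% failures
aborting the run. Intervals are 2.5/97.5 percentiles.

## Synthetic data generator

The generator emulates: a weighted cross-sectional adult diet survey
(default 586 participants aged 18–80, lognormal mean-1 survey weights);
food records with lognormal grams/day averaged over 4 diary days
(day-to-day variability is exposed as `day_to_day_cv` since its true
structure is not identified); category salt content at target × (1 +
excess) with truncated-normal excess (mean 0.25, 90% of foods strictly
above target), which guarantees a nonnegative intervention effect with
tunable size; ~10% homemade and ~20% unmatched records; 20% of matched
records out-of-home with per-serving targets; men logging ~1.2× and
women ~0.8× the mean record count, giving a larger male reduction.
These defaults put the diary-estimated baseline near 5.2 g/day and,
with the default 1.16 under-reporting factor, the corrected baseline
near 6.1 g/day with an ~18% full-compliance reduction — the intake
regime the analysis is designed for. Reference intakes are constructed
as survey mean × true factor per stratum, so the correction stage must
recover the configured truth exactly.

Epidemiology is generated on single-year ages 0–110 with Gompertz-like
age slopes; prevalence and cause-specific mortality are derived by
forward-simulating the same 3-state process the engine uses, so the
inputs are mutually consistent by construction and pass the engine's
validator with no adjustment. All-cause mortality is other-cause plus
the derived cause-specific rates, so mortality dominance holds exactly.
Trend histories are exact log-linear series, so the trend estimator
recovers the configured factors to machine precision.

What the generator does not emulate: real food nomenclature or category
granularity, survey cluster/stratum design, correlation between intake
level and under-reporting, within-category salt heterogeneity tied to
brands, cohort effects in disease rates, or costs that vary with age
and severity. Passing tests therefore demonstrate correctness of the
*machinery* (arithmetic, calibration recovery, lifetable dynamics,
uncertainty propagation) on data with the assumed structure — not the
realism of any particular published estimate.

## Numerical choices and degenerate inputs

- Rate → probability via 1 − exp(−rate), keeping probabilities in [0,1]
  for any nonnegative rate.
- Exposure prevalences renormalized after truncation at ±6 SD; PIF of a
  zero shift is exactly 0; a whole population below the TMREL gives
  PIF = 0.
- Strata with no persons are omitted from calibration with a warning;
  a zero stratified mean makes the correction factor undefined (error).
- Persons with no qualifying food records have intake 0.
- A degenerate parameter CI (low = high = central) is a point mass.
- Horizons beyond the oldest cohort's remaining lifetime are truncated
  with a warning.
- Problem sizes used by the test suite are scaled to keep it quick:
  200-person surveys, 100-replicate bootstraps, tens of Monte Carlo
  iterations for pipeline behaviour (10,000 draws are still used where
  the check is about interval calibration of a single parameter), and a
  200,000-individual microsimulation oracle on two cohorts over 20
  years with common random numbers.

## Known limitations

- No consumer-behaviour response: quantities eaten are fixed; only salt
  content changes (the shortfall variants proxy partial compliance).
- The under-reporting correction also captures discretionary salt,
  which reformulation does not touch; the `no_underreporting` variant
  bounds this from below.
- Independent diseases: no multimorbidity disutility or cost
  interaction; additive utility decrements.
- No uncertainty on baseline epidemiology (incidence, case fatality,
  prevalence) — only on the intervention pathway and valuation inputs.
- The linear salt–BP slope is assumed homogeneous across subgroups.
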