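# Methods

## The estimand

Lifetime risk of surgery is the probability that a newborn, exposed for
their whole life to today's age- and sex-specific surgery and mortality
rates, undergoes at least one surgical procedure before dying. It is a
*period* measure: a hypothetical cohort is pushed through current
cross-sectional rates, exactly as a period life expectancy is constructed.
Two event definitions are carried through every stage: **first surgery**
(each person counted once, at their first documented procedure) and **all
surgery** (every procedure, so one person can contribute several events and
the band-level event rate can exceed the first-surgery rate).

## From counts to rates

Inputs are three annual tables stratified by sex and the 19 five-year age
bands 0–4 … 85–89, ≥90: event counts (with an optional per-row category tag
used by the obstetric-exclusion sensitivity analysis), mid-year population,
and all-cause deaths. Person-years for a period are the sum of mid-year
populations × 1 year over its calendar years — the standard demographic
exposure approximation. Rates for a multi-year period are pooled
(Σ events / Σ person-years), not averages of yearly rates, so they are
invariant to how the period is split. Zero person-years with nonzero events
is an error; with zero events it yields a zero rate and a warning.

## Life-table estimator (primary)

Within band x of width n_x the surgery hazard λ_x and mortality hazard μ_x
are taken constant, so waiting times are exponential and death is a
competing risk. For a person entering the band surgery-free:

* probability of first surgery in the band:
  a_x = (λ_x/h_x)·(1 − e^{−h_x n_x}), where h_x = λ_x + μ_x;
* probability of reaching the next band alive and surgery-free:
  s_x = e^{−h_x n_x}.

The open ≥90 band is followed to extinction: a = λ/(λ+μ), s = 0 — the
first-passage probability of competing exponentials. A radix-l₀ cohort
yields d_x = l_x·a_x expected first surgeries and cumulative risk
Σ_{y≤x} d_y / l₀; the last band's cumulative risk is the lifetime risk.
Results are radix-invariant (tested); the default radix 100 000 is purely
conventional.

The rate→probability conversion is a pluggable strategy. The exponential
form above is the default; a Chiang-type actuarial form
q = n·h/(1 + n·h/2) is available (`conversion="chiang"`) for sensitivity
checks — the two differ only in the second decimal at realistic rates.

"All surgery" lifetime risk reuses the same first-passage formulae with the
inflated all-event rate: it is interpreted as the risk of at least one
surgery under that rate, which keeps it below 100% while exceeding the
first-surgery risk, matching how the two are reported side by side.

## Cumulative-incidence estimator

The alternative estimator ignores mortality entirely:
1 − exp(−Σ_x λ_x·ñ_x), with ñ_x = n_x for finite bands and a truncated
width for the open band (default 10 years, i.e. follow-up to about age
100, configurable because no canonical truncation exists). Removing the
competing risk of death makes it an upper bound on the life-table value for
any realistic schedule; with a very long truncation and no mortality the two
estimators coincide (tested).

## Uncertainty

* **Multi-year periods** (k ≥ 2 years): the estimate is the arithmetic mean
  of the yearly lifetime risks; the CI is mean ± t_{(1+level)/2, k−1}·SD/√k.
  A t-interval is used because k is tiny (4 pre-pandemic years); the per-band
  risk curve is averaged bandwise the same way.
* **Single years**: a parametric bootstrap — event and death counts in every
  stratum are independently redrawn as Poisson with the observed counts as
  means (person-years fixed), the lifetime risk recomputed each replicate
  (vectorised over replicates), and the percentile interval taken. Defaults:
  5000 replicates, fixed seed; deterministic given the seed. Calibration is
  verified by a 200-registry coverage simulation in the test suite.
* **Period comparison**: absolute change (percentage points), relative
  change (% of the pre value), CI overlap, and a two-sided paired t-test.
  The pairing unit is the age band (19 pairs): the pre and post cumulative
  risk curves are differenced bandwise. The pairing unit is recorded in the
  output, since band-level pairs are serially correlated (cumulative sums),
  so the p-value should be read as a descriptive contrast of curves rather
  than a strict test of independent pairs.

Presentation rounding is round-half-up — risks to one decimal, relative
changes to the nearest integer — and is applied only at the reporting layer;
all internal arithmetic is full precision.

## Synthetic registry generator

The generator stands in for restricted hospital-episode and national
population/mortality data. Each individual lives under piecewise-constant
hazards: mortality μ_x, first-surgery λ_x acting on the surgery-naive, and,
after a first surgery, repeat procedures as a homogeneous Poisson process
ρ_x. The exact first-passage probability Σ_x S_x·(λ_x/h_x)(1 − e^{−h_x n_x})
(open band: S·λ/h) is exposed as `analytic_lifetime_risk`, and a brute-force
Monte-Carlo estimate with binomial standard error as `mc_lifetime_risk`;
these are the oracles against which the estimators are tested.

**Stationary-population convention.** Each (sex, calendar year) pair is an
independent cross-section, as a real annual registry would observe:
`cohort_size` surgery-naive individuals are drawn from the equilibrium age
distribution implied by the hazards (density ∝ exp(−∫(λ+μ))), followed for
one year, and first surgeries, surgery-free deaths and surgery-free
person-years are tallied by the band in which they occur. Repeat procedures
are added at the stationary aggregate level: Poisson counts with mean
(birth rate) × ρ_x × (post-surgery person-years per cohort life), the
exposure estimated from an auxiliary whole-life cohort. Sampling uses exact
inverse-transform inversion of the piecewise-linear cumulative hazard; one
independent RNG stream per (sex, purpose, year) is split from the master
seed, so adding a sex or year never perturbs another stream's draws.

Because the emitted population and death tables track the *surgery-naive*
population, the per-capita rates the pipeline computes are unbiased for the
generative hazards, and the full pipeline recovers the analytic lifetime
risk (tested to within three bootstrap standard errors at cohort size
10⁵). This is a deliberate idealisation: real national denominators count
everyone, naive or not, and with a ~60% lifetime risk the naive share of
person-years is far below one in later life. Dividing first surgeries by
whole-population person-years understates the naive hazard substantially
(about 19 percentage points of lifetime risk under the default schedules).
Passing recovery tests therefore demonstrate that the estimator is correct
*under its own assumption* that the event rate approximates the event
hazard among the susceptible — not that estimates from real whole-population
denominators are unbiased for a cohort probability.

**Default parameters.** Mortality is a stylised Gompertz-like schedule with
infant excess (0.08% at 0–4 falling to 0.01%, rising to 21%/25% per year at
≥90 for women/men). First-surgery hazards are calibrated so the analytic
lifetime risks equal 60.2% (women) and 59.1% (men) — the reported national
magnitudes — with the female excess concentrated in the reproductive ages.
Recurrence rates (0.015/yr women, 0.024/yr men, flat in age) put the
all-surgery lifetime risk near 80% for both sexes. The obstetric fraction
of female events peaks at 35% in ages 25–34 and is zero for men. Defaults:
cohort 100 000 per sex-year, years 2016–2020. A `pandemic_scenario` helper
scales the surgery (and recurrence) hazards by 0.66 and mortality by 1.15
for chosen years, giving the period comparison a known direction of effect.

What the generator does **not** emulate: whole-population denominators (see
above), migration, secular trends within a period, seasonality, the HES
coding artefact that removes some male infants together with obstetric
episodes, hospital-level structure, and dependence of mortality on surgical
status.

## Numerical and design notes

* Age bands are closed–open [lower, lower+n) in years; age at event is age
  on the date of the procedure; exactly the last band is open-ended.
* Zero total hazard in a finite band gives a = 0, s = 1; in the open band it
  is flagged as an immortal event-free tail (a = 0 with a warning).
* Tie-breaking in the largest-successive-increase contrast prefers the older
  epoch pair, with a 10⁻⁹ absolute tolerance so that printed-value ties are
  recognised despite floating-point noise.
* `compare_periods` with zero-variance nonzero differences reports t = ±∞
  and p = 0 with a warning; identical curves give t = 0, p = 1.
* Input files are comma-separated UTF-8 with fixed headers; sex is a strict
  two-level factor F/M; structural violations raise a parse error naming
  file and field, while grid completeness findings accumulate in a
  validation report.
* Problem sizes in the test suite (10⁶-individual Monte-Carlo checks,
  200-registry coverage at cohort 20 000, recovery at cohort 10⁵ × 4 years)
  were chosen so each check resolves the quantity it tests to well inside
  its tolerance.

## Known limitations

* The per-capita-rate approximation discussed above is inherited from the
  method itself; no susceptible-denominator correction (of the kind used in
  current-probability cancer-risk software) is applied.
* Mortality rates are whole-population all-cause rates; whether the
  surgery-free population's mortality differs is not modelled.
* The paired t-test's band-level pairs are serially correlated; the p-value
  is descriptive.
* A single pre-specified comparison is reported; no multiplicity control,
  Bayesian intervals, or trend analysis.
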