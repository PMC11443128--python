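# surgrisk

Lifetime risk of surgery from age- and sex-stratified registry tables.

`surgrisk` estimates the probability that a newborn will undergo a surgical
procedure at some point in their life, given current age-specific surgery
and mortality rates — the "lifetime risk of surgery" familiar from national
hospital-episode analyses. It is aimed at epidemiologists and health-service
researchers who have (or can emulate) three annual tables stratified by sex
and 5-year age band (0–4, 5–9, …, 85–89, ≥90):

* surgical event counts (every procedure, and each patient's *first*
  procedure, with an optional category tag such as `obstetric`),
* mid-year population counts,
* all-cause death counts.

Because the real inputs of such analyses (hospital-episode extracts, national
population and mortality releases) are access-restricted, the package ships a
synthetic registry generator with analytic ground truth, so the entire
pipeline is testable end to end.

## Methods

**Life-table method (primary).** Counts become occurrence/exposure rates
λ_x (surgery) and μ_x (all-cause mortality) per person-year in each age band
x. Treating hazards as constant within a band of width n_x, the probability
of a first surgery while in the band, for someone entering it surgery-free,
competes with death:

    a_x = (λ_x / (λ_x + μ_x)) · (1 − e^{−(λ_x+μ_x) n_x}),   s_x = e^{−(λ_x+μ_x) n_x}

with the open ≥90 band followed to extinction (a = λ/(λ+μ), s = 0). A cohort
of radix l₀ = 100 000 is run down the table, d_x = l_x·a_x first surgeries
accumulate, and the lifetime risk is Σd_x / l₀.

**Cumulative-incidence method.** Ignores competing mortality:
1 − exp(−Σ λ_x·n_x), with the open band truncated (default 10 years,
i.e. follow-up to ≈ age 100). It bounds the life-table estimate from above.

**Inference.** Multi-year (e.g. 2016–2019) estimates are yearly means with a
t-interval (k−1 df); a single year gets a parametric-bootstrap CI (counts
redrawn as Poisson); pre- vs pandemic-period contrasts report absolute and
relative change, CI overlap, and a two-sided paired t-test across the 19
age bands.

## Worked example

Simulate the default synthetic registry (100 000-person cross-sections per
sex-year, 2016–2020, with surgery hazards scaled by 0.66 and mortality by
1.15 in 2020), then estimate and compare periods for women:

```python
import surgrisk as sr

spec = sr.pandemic_scenario(sr.CohortSpec(cohort_size=100_000, seed=1))
reg = sr.simulate_registry(spec)

yearly = []
for year in (2016, 2017, 2018, 2019):
    rates = sr.build_rate_table(reg.events, reg.population, reg.deaths, [year], "first")
    lt = sr.build_life_table(rates, sex="F")
    yearly.append(sr.lifetime_risk_lifetable(lt, sex="F", period=str(year)))

pre = sr.average_years(yearly)
post = sr.single_year_ci(reg.events, reg.population, reg.deaths, 2020, "F", seed=1)
comp = sr.compare_periods(pre, post)
```

This prints (formatted):

```
pre-pandemic lifetime risk : 60.1% (95% CI 59.1-61.2)
generating truth           : 60.2%
pandemic-year risk         : 43.4% (95% CI 40.9-45.8)
absolute change            : 16.8 points
relative change            : 28%
paired t-test              : t=7.93, p=2.78e-07
```

The pre-pandemic estimate recovers the generator's analytic lifetime risk
(60.2%); the suppressed 2020 surgery rates show up as a large, significant
drop in lifetime risk — the qualitative signature reported for the real
pandemic year.

The same analysis is available from the shell:

```
surgrisk simulate --out registry/ --cohort-size 100000 --seed 1 --pandemic-year 2020
surgrisk compute --events registry/events.csv --population registry/population.csv \
    --deaths registry/deaths.csv --pre 2016-2019 --post 2020 --seed 1 --out results/
```

which writes `rates.csv`, per-stratum life tables, a Table-1-shaped
`estimates.csv` (19 bands × 2 sexes × 2 event definitions) and
`comparison.json`.

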