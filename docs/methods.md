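# Methods

## The estimation problem

The target quantity is the annual economic burden of illness attributable to
surface-water recreation in the US: how many recreation events occur, how
many excess illnesses they cause, how severe those illnesses are, and what
they cost. No single data source covers that chain, so the model combines
national recreation surveys (exposure), prospective cohort studies of
swimmers and incidental-contact recreators (illness probabilities and
healthcare utilization), passive outbreak surveillance (severe outcomes),
and standard unit-cost sources, and propagates the uncertainty of every
input by Monte Carlo simulation. All dollar figures are in 2007 USD, the
year in which the main data sources overlap.

## Pipeline

### Exposure

One *recreation event* is one person-day of one activity. For activity *a*:

    recreators_16plus_a = participation_a × N_adults
    recreators_under16_a = share_a × N_children
    events_a = (recreators_16plus_a + recreators_under16_a) × days_a

with `N_adults` the non-institutionalized population aged ≥ 16 (233.5M in
2007) and `N_children` the population under 16 (63.3M). `share_a` is the
fraction of the under-16 population engaging in the activity (the printed,
checkable convention); a helper for the alternative cohort-ratio convention
(children per adult recreator) exists but is not on the default path.
Fishing covers warm-water fishing only.

### Sporadic illness

For each declared (activity, illness) pair the attributable risk is the risk
difference `AR = p_exposed − p_unexposed`, both probabilities per recreation
event over the cohort recall window, and annual cases are `events_a × AR`.
Pairs with no observed excess risk are *absent* from the scenario: they
contribute zero cases and, deliberately, zero variance. Cohort confidence
intervals that cross zero produce negative AR draws; these propagate into
the totals by default (`truncate_negative_ar: false`). The truncation
switch floors each AR draw at zero; it can only raise mean case counts, and
on the packaged scenario it moves the mean total cost by well under 5%.

Cases split into **mild** (no healthcare contact) and **moderate** (HCP or
ED contact) by an illness-specific moderate fraction (7.2% for AGI up to
24.3% for ear illness). The fraction is activity-invariant because it is
only reported per illness type.

### Severe illness

Severe illness (hospitalization or death) is estimated from passive outbreak
surveillance, which captures a small fraction of community cases. Per
pathogen:

    community = observed × multiplier
    hospitalizations = community × hosp_fraction × 2
    deaths = community × death_fraction × 2

The community multiplier is 25.5 in general (from foodborne-illness
validation work, applied on the reading "total = observed × 25.5"; the
alternative ×26.5 reading is reachable by editing the config), 1.1 for
vibriosis (whose single cases are already captured), and 1.0 for *Naegleria
fowleri* (primary amoebic meningoencephalitis is nearly always fatal and
diagnosed, `death_fraction ≈ 1`). The final ×2 corrects for underdiagnosis
of hospitalizations and deaths themselves. Outcome fractions are applied to
the community-multiplied counts; applying them to laboratory-confirmed
counts before multiplication is the other defensible order and would scale
severe outcomes by the same multipliers. Severe cases are additional to the
sporadic mild/moderate counts (separate estimation paths, no subtraction).

### Costs

Per severity tier *i*:

    Cost_i = OTC_i + Rx_i + HCP_i + ED_i + Hospital_i
             + Sequelae_i + Productivity_i + VSL_i

Mild cases incur OTC medication, prescriptions, and lost productivity;
moderate cases add HCP and ED visits; severe (per hospitalized case) incur
all eight, with hospital stays costed per pathogen, sequelae
(hemolytic-uremic syndrome for *E. coli* O157, Guillain–Barré syndrome and
reactive arthritis for *Campylobacter*, reactive arthritis for *Shigella*)
costed among hospitalized cases, and deaths monetized at the value of a
statistical life (VSL, applied uniformly — the age distribution of severe
outcomes is unknown). Productivity is `cases × P(work loss) × lost hours ×
wage`; VSL is taken to subsume the lost productivity of the deceased.
`inflation_adjust` converts amounts between dollar-years using CPI factors
keyed by (year, series), with series for medical commodities, medical
services, and wages; the 2007 factors are 1 by construction.

### Monte Carlo

Each iteration draws one value per parameter and evaluates the pipeline;
outputs are summarized as mean and C90 (empirical 5th/95th percentiles,
linear interpolation between order statistics, numpy's default convention).
Parameters are drawn independently across parameters and iterations in a
fixed, documented order (activities → risks → severity profiles → pathogens
→ cost inputs, each in declaration order, one block of *n* variates per
parameter), making runs bit-reproducible for a given (scenario, n, seed).
Default n = 100,000 (≈ 1.5 s on one CPU, vectorized). No correlation
structure, variance reduction, or quasi-random sampling is used.

## Distribution conventions

Uncertain parameters are declared as `DistributionSpec`s (point, uniform,
normal, truncated normal, triangular, PERT, lognormal, empirical). Two
conventions matter:

- **Interval inversion.** A quantity reported as mean with a central-90%
  interval becomes a normal with `sd = (p95 − p5) / (2 × 1.6449)` (YAML key
  `c90`); one reported with a 95% CI uses `sd = (hi − lo) / (2 × 1.96)`
  (key `ci95`). The cohort illness probabilities carry 95% CIs; the
  survey-derived exposure inputs carry C90s.
- **Truncation by clipping.** Proportions are clipped into [0, 1] and
  costs/days/hours into [0, ∞) *after* sampling, rather than resampled, so
  exactly one variate is consumed per parameter per iteration regardless of
  where truncation binds — this is what keeps seeded runs reproducible when
  a bound moves. Attributable risks are intentionally not clipped (the
  negative tail is part of the main analysis). `analytic_mean` accounts for
  clipping exactly (closed form for normals, quadrature otherwise), which
  the synthetic oracle relies on.

## The packaged 2007 scenario

`src/aquaburden/data/us2007.yaml` encodes the published national inputs: the
two census population bases; six activities with participation, under-16
share, and days per recreator (all with C90s); thirteen (activity, illness)
risk pairs with exposed/unexposed probabilities (95% CIs); and the five
moderate-severity fractions.

The remaining inputs are published only at aggregate level, so the file
carries **calibrated reconstructions**, labelled as such: nine pathogen
records (observed counts, outcome fractions, hospital cost), healthcare
utilization probabilities per tier, lost-work hours, unit costs, and a
lognormal VSL (mean $7.4M, log-sd 0.55, giving the mortality cost its long
right tail). Calibration was analytic — unit values chosen so the
point-mean pipeline reproduces the published tier-level cost components
(e.g. mild OTC: 80.2M mild cases × 50% use × $6.04 ≈ $242M; severe:
~807 hospitalizations and ~30.4 deaths × $7.4M ≈ $225M mortality cost) —
not a fit to simulation output. These reconstructions reproduce aggregate
published behaviour by construction; they are not pathogen-level or
price-level evidence, and conclusions at that granularity should not be
read off them.

## Synthetic scenarios and what the tests show

`generate_scenario(seed, ...)` emits random, schema-valid scenarios with
realistic magnitudes (participation ≤ 0.5, implied ARs in [−0.01, 0.05],
multipliers from {1, 1.1, 25.5}, severe fractions ≤ 0.3), mixing
distribution families so every sampler is exercised. Because every reported
cell is a sum of products of independent draws, its exact expectation is the
same product chain evaluated at per-parameter analytic means;
`analytic_expectation` returns that truth table, and the test suite checks
the simulated mean of every cell against it within 4 Monte Carlo standard
errors (and exactly, for point-mass scenarios). Ratio outputs (moderate
share, per-case costs) are excluded from the truth table since the
expectation of a ratio is not the ratio of expectations.

What passing does **not** show: the generator draws the parameter book, not
person-level outcomes, so it validates the propagation arithmetic — it says
nothing about whether the cohort risk estimates transport to all US waters
(site selection bias toward fecally impacted waters, risk-perception bias,
multi-illness overlap are all real-data concerns outside this model).

## Design choices in genuinely open territory

- Exact distribution families of the original inputs are unknown; any
  mean-plus-interval quantity defaults to a (truncated) normal, consistent
  with the symmetric published intervals. Reconstructed fractions use PERT,
  reconstructed counts and costs normals with ~±25% C90s.
- `p_exposed` and `p_unexposed` are sampled independently (their cohort
  covariance is unpublished); this widens the AR spread slightly relative
  to sampling the AR directly from its CI.
- Moderate-tier utilization is an explicit override of the mild
  probabilities (pooled utilization is published only across all cases).
- Severe-tier OTC/Rx/HCP/ED micro-costs are modeled per hospitalized case
  at the same unit costs, with utilization capped at probability 1. The
  published severe HCP micro-component (~$0.16M) implies more than one
  visit per stay and is under-reproduced (~$0.06M); the discrepancy is
  0.04% of the severe tier and is accepted rather than introducing
  visit-count semantics.

## Limitations

- Per-case ratios inherit a slight downward shift relative to published
  means (ratio of correlated draws), well inside the published intervals.
- No age stratification, geographic/seasonal disaggregation, co-morbidity,
  harmful-algal-bloom exposure, or outpatient reactive arthritis; no payer
  decomposition or discounting.
- The central-90% interval of the simulated grand total is marginally wider
  at the low end than published, consistent with the independence and
  normality defaults above.
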