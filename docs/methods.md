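# Methods

## The cohort-construction model

The package implements a cross-sectional cohort of adults drawn from the
structured tables of a multi-site EHR/claims common data model: persons,
enrollment spans, vitals, labs, encounter diagnoses (ICD-9-CM), procedures
(CPT-4 / HCPCS / ICD-9 procedure), medication dispenses, geocode links and
census block-group profiles. The study period is ICD-9-era (2012–2013 by
default) and all intervals are closed calendar-date intervals; "at least 12
months of continuous membership" is operationalized as ≥ 365 covered days
of merged enrollment inside the window, since day counting is unambiguous
across month lengths. Span merging bridges gaps of at most
`gap_tolerance_days` uncovered days (default 0 — "continuous" taken
literally; the bridging rule varies across claims shops, so it is a
configuration knob rather than a constant).

One site may be flagged *safety-net*: such systems provide care regardless
of coverage and do not enroll members, so eligibility there is
encounter-based (≥ 1 primary-care encounter in the window) instead of
enrollment-based. Because no table in the common set stores bare
encounters, the package adds an `encounters` table (person, date, type);
only `primary_care` encounters confer eligibility.

### Exclusion order and attribution

Exclusions run in a fixed order — age, missing anthropometrics, pregnancy,
implausible values, BMI threshold — and each person is attributed to the
first step they fail. This makes the attrition flow conserve exactly
(entering = final + Σ exclusions), which the reporting layer enforces: a
flow report refuses to print a non-conserving flow rather than rebalance
it. The *final cohort membership* is invariant to the step order; only the
per-step attribution depends on it.

Two operationalizations deserve note:

- *Missing height/weight* is judged on the raw record: a person passes if
  they have an in-window recorded BMI, or an in-window weight plus a height
  anywhere in their record (heights are long-lived measurements; weights
  and recorded BMIs must be current). A person whose only anthropometric is
  a recorded BMI therefore passes this step and can fall only at the
  plausibility step.
- *Pregnancy* has no canonical source field; the package accepts a
  precomputed per-person flag table, or derives the flag from a
  configurable ICD-9 prefix list (default V22, V23, 630–679) on in-window
  diagnoses. The mechanism is explicit and swappable because source
  cohorts rarely state theirs.

### Anthropometrics

Canonical units are metres, kilograms and kg/m²; imperial values are
converted once at ingestion with exact factors (1 in = 0.0254 m, 1 lb =
0.45359237 kg), so every later comparison runs on a single unit system.
Plausibility bounds are half-open — height [1.2192, 2.4384) m (4–8 ft),
weight [22.6796185, 453.59237) kg (50–1000 lb), BMI [5, 90) — because the
defining rules exclude "less than" the lower limit but "equal to or greater
than" the upper one. BMI categories are a half-open partition at
23/25/30/35/40/50; placing the class-3/4 boundary as [40, 50) / [50, 90)
leaves no gap and no overlap between the two printed variants of that
boundary. Ties among same-day vitals are broken by ingestion ordinal so
re-runs are deterministic.

## Phenotype rules

All thresholds and code lists live in configuration, never in code. The
diabetes rule requires its two "other" events on distinct calendar dates
(default; toggleable): a single encounter can generate an outpatient code
and a lab on the same day, and counting that once follows the surveillance
convention the rule derives from. The same toggle governs the two
outpatient hypertension codes. No maximum separation is imposed between
the two events — the study window already bounds it. Pre-diabetes bands
are inclusive on both endpoints ("between x and y"); diabetes thresholds
are inclusive ("equal or greater"). The OGTT band applies to the 2-hour
post-load glucose, the value on which the 140–199 mg/dL band is defined.
Bariatric codes are matched exactly (procedure codes are not hierarchical
the way diagnosis prefixes are) over a 2009–2013 lookback.

Diagnosis-prefix matching respects the sub-code boundary: "401" matches
"401", "401.9", "401.91" but never "4011"; a dotted prefix like "790.2"
extends by trailing digits ("790.21"). An empty pattern set raises instead
of silently matching nothing, to catch misconfigured code lists.

The Charlson map ships as the classic 17-condition Deyo ICD-9-CM weighting
with three hierarchy pairs (complicated diabetes > diabetes, moderate/severe
liver > mild liver, metastatic > solid tumour); a site using an extended
condition list supplies its own map — the map is data. A validation helper
warns when two non-hierarchy conditions share a prefix boundary.

## SES estimation

Person-level education and income are expectations under the person's
block-group probability profile: Σ p(level)·value(level), with the numeric
value per census level supplied in configuration (defaults: years of
schooling 10–18 across five attainment bins; income band midpoints
$12.5k–$175k across six bins). Members without a geocode, or pointing at an
unknown block group, are flagged `no_geocode` and never imputed. Estimates
are bounded by the extreme level values and scale linearly with them.

## Survey design

Per site, simple random samples without replacement of 135 each from the
overweight, obese-1 and obese-2 strata and 270 from the pooled obese-3+
stratum (675/site; 5,400 across 8 sites). Healthy-weight members are never
sampled. Sampling is seeded and order-invariant: cells are visited in a
fixed (site, stratum) order and drawn from person-id-sorted lists, so the
same seed reproduces the same sample regardless of input row order. An
undersized cell raises an error naming the cell and its shortfall.
Percentages everywhere are 100·n/d rounded half-away-from-zero to two
decimals, the convention that reproduces every printed ratio checked during
development; response rates divide completed surveys by sampled minus
ineligible, and per-group response tables use each group's sampled n as
denominator.

## The synthetic-data generator

The generator emulates the *statistical structure the pipeline assumes*,
not clinical reality. Each person draws independent flags — membership
failure, missing measurements, pregnancy (women 18–49), implausible vitals,
BMI band, glycemic state, hypertension, bariatric history, comorbidities —
and events are then constructed to satisfy or violate the corresponding
rule exactly: a diabetic receives an inpatient code or two qualifying
events on distinct dates; an implausible person receives one vital drawn
uniformly just outside its bound, arranged so the person passes the
missing-measurement step and fails plausibility; background labs are drawn
strictly inside normal ranges and background diagnoses from codes no rule
matches, so no phenotype can arise by accident. The BMI model is a mixture
over category bands (band probability × uniform within band): right-skewed,
and it makes the planted per-category counts a sharp oracle for the
classification and flow engine.

Default rates are chosen to reproduce the attrition geometry and
prevalences of a large insured adult population: ~22 % of entering members
under 18 (via a clipped-normal age distribution, mean 38, SD 23), ~20 % of
adults without usable height/weight (weight-in-window 0.78, height 0.85,
recorded-BMI 0.40), pregnancy 9 % among women 18–49 (~2.8 % of remaining
adults), implausible 0.11 %, ~14.9 % of valid adults below BMI 23, and
cohort prevalences of 29.49 % pre-diabetes, 14.98 % diabetes, 34.33 %
hypertension, 0.48 % bariatric history; 60 % of eligible members also hold
2009 enrollment (the retrospective "nested" subgroup). Site demographics
default to the pooled race/ethnicity and insurance mix of such a
population.

The generator's manifest records its own first-failing-step accounting and
per-category/phenotype counts; the test suite asserts the pipeline
reproduces these *exactly*, and a brute-force oracle (naive pair
enumeration, independent prefix matcher) re-evaluates every phenotype on
small populations.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: longitudinal trajectories, correlation
between comorbidities beyond the configured marginals, realistic code
frequency profiles, coding errors other than the planted implausible
values, site-level heterogeneity in testing rates, and any biophysical link
between BMI and disease. Recovery of planted prevalences demonstrates the
rules engine is faithful, not that the rules are valid clinically.

## Numerical choices and degenerate inputs

- Percent arithmetic uses decimal arithmetic (not binary floats) before
  rounding, so half-cases round away from zero exactly.
- `classify_bmi` refuses values outside [5, 90): plausibility filtering is
  a precondition, not a silent clamp.
- Empty event lists yield negative phenotypes, zero Charlson, and
  ineligible enrollment — never errors; an empty *person* table is an
  error.
- Computed BMI uses the same float expression in the vectorised pipeline
  and the per-person API (w/h²) so both paths agree bit-for-bit.
- Seeds: the generator consumes a single numpy `default_rng(seed)` stream
  in a fixed order, giving byte-identical CSV output per (config, seed).

## Problem sizes

The shipped tests run the full pipeline at 1,200–50,000 synthetic persons
(the 50,000-person run checks prevalence recovery within three binomial
standard errors), 100 randomized small configurations for flow
conservation, and brute-force oracle comparison at ≤ 1,000 persons; the
acceptance script uses 88,000 persons (11,000 × 8 sites) so that every
site's pooled obese-3+ survey cell comfortably exceeds its 270-person
allocation. These sizes were chosen as the smallest that make the binomial
tolerances sharp.

## Known limitations

- ICD-9 only; the study period predates ICD-10 in US claims.
- The 22-condition variant of the comorbidity index used by some cohort
  reports is not publicly enumerated; the default map is the classic
  17-condition scheme and extended maps must be supplied as data.
- Pregnancy detection by diagnosis prefix is a proxy; registry- or
  lab-based ascertainment would differ.
- SES expectations are ecological (block-group means), not individual
  measurements, and the income domain does not distinguish family from
  household income distributions.
- No weighting or nonresponse adjustment is applied to survey results.
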