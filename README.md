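# ehrcohort

Construction of a multi-site, cross-sectional **adult overweight/obesity
cohort** from electronic-health-record (EHR) tables, with computable
phenotypes, neighborhood socioeconomic estimation, stratified survey
sampling — and a seeded synthetic EHR generator so the whole pipeline is
testable end-to-end without access to protected health data.

The package is aimed at epidemiologists and health-services researchers who
build claims/EHR cohorts across health systems with a common data model:
the eligibility accounting, anthropometric plausibility rules, and
rule-based condition definitions implemented here are the standard building
blocks of that work, encoded as configuration rather than buried in site
SAS programs.

## What it computes

**Cohort eligibility and attrition.** Members with ≥ 12 months of
continuous (gap-mergeable) enrollment intersecting the 2012–2013 study
window — or, for a safety-net system without defined membership, at least
one in-window primary-care encounter — pass through ordered exclusions:
age < 18 on 2013-12-31, no usable height/weight, pregnancy, implausible
vitals, BMI < 23.0 kg/m². Each person is attributed to the *first* failing
step, so the flow chart conserves counts exactly.

**Anthropometrics.** Heights outside [4 ft, 8 ft), weights outside
[50 lb, 1000 lb) and BMI outside [5, 90) kg/m² are implausible and removed.
The most recent in-window recorded BMI wins; otherwise BMI = weight/height²
from the latest in-window weight and the latest height anywhere in the
record. Categories use half-open bands with the WHO Asian-aware lower cut
point: healthy [23, 25), overweight [25, 30), obese class 1 [30, 35),
class 2 [35, 40), class 3 [40, 50), class 4 [50, 90).

**Computable phenotypes** (all code lists and thresholds are config data):

- *diabetes* — surveillance rule: 1 inpatient diabetes diagnosis, or any 2
  other qualifying events on distinct dates (outpatient diagnosis,
  anti-hyperglycemic dispense, HbA1c ≥ 6.5 %, FPG ≥ 126 mg/dL,
  RPG ≥ 200 mg/dL);
- *pre-diabetes* — one in-band lab (HbA1c 5.7–6.4 %, FPG 100–125,
  2-h OGTT 140–199, endpoints inclusive) or an outpatient 790.2x code,
  superseded whenever the diabetes rule is met;
- *hypertension* — ≥ 2 outpatient (distinct dates) or ≥ 1 inpatient
  401–405 diagnosis;
- *bariatric surgery* — exact CPT-4/HCPCS/ICD-9-procedure code match over
  a 2009–2013 lookback;
- *Charlson comorbidity score* — weighted condition sum with hierarchy
  supersession (17-condition Deyo map shipped as a default).

**SES estimation.** Expected education (years) and income (dollars) as the
mean of configured level values under each member's census block-group
probability profile.

**Reporting and survey.** Flow reports, site-level prevalence tables with
two-decimal percentages (half-away-from-zero), cross-site ranges, a
stratified survey sample (per site: 135/135/135 from overweight and obese
classes 1–2 plus 270 from pooled class 3+, i.e. 675 × 8 sites = 5,400),
and response-rate tables.

## Worked example

```python
from ehrcohort import (Config, SimulationConfig, build_cohort, default_sites,
                       flow_report, generate_population, phenotype_all)

tables, _ = generate_population(SimulationConfig(seed=42, sites=default_sites(500, 8)))
cfg = Config(safety_net_sites=("dh_08",))
members, flow = build_cohort(tables, cfg)
print(flow_report(flow).to_string(index=False))
```

prints

```
                              step  excluded  remaining
         eligible members entering         0       3808
         less than 18 years of age       715       3093
     no height and weight recorded       634       2459
  pregnant during the study window        68       2391
implausible height, weight, or BMI         4       2387
              BMI below 23.0 kg/m2       368       2019
```

3,808 of the 4,000 generated persons are eligible members; ordered
exclusions leave a cohort of 2,019 adults with BMI ≥ 23 kg/m². Phenotyping
the same cohort (`phenotype_all(members, tables, cfg)`) yields prevalences
of 15.21 % diabetes, 28.03 % pre-diabetes, 35.81 % hypertension and 0.54 %
bariatric history — close to the generator's planted rates of 14.98 %,
29.49 %, 34.33 % and 0.48 %, and converging to them as the population
grows. The `examples/` directory has one short script per capability
(generation, cohort build, phenotypes, SES, survey sampling).

A thin CLI mirrors the library: `ehrcohort simulate`, `build-cohort`,
`phenotype`, `report`, `sample-survey` (see `ehrcohort --help`).

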