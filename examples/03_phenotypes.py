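"""Evaluate computable phenotypes for cohort members and report prevalences.

Diabetes follows the surveillance two-event rule, pre-diabetes the in-band
lab / 790.2x rule with supersession, hypertension the 2-outpatient-or-1-
inpatient 401-405 rule, bariatric surgery an exact procedure-code lookback,
and the Charlson score a weighted comorbidity sum.
"""

from ehrcohort import Config, SimulationConfig, build_cohort, default_sites, generate_population, percent, phenotype_all

tables, _ = generate_population(SimulationConfig(seed=42, sites=default_sites(500, 8)))
cfg = Config(safety_net_sites=("dh_08",))
members, _ = build_cohort(tables, cfg)
phen = phenotype_all(members, tables, cfg)

n = len(phen)
glyc = phen["glycemic_status"].value_counts()
print(f"cohort members:       {n}")
print(f"diabetes:             {glyc.get('diabetes', 0)} ({percent(int(glyc.get('diabetes', 0)), n)}%)")
print(f"pre-diabetes:         {glyc.get('prediabetes', 0)} ({percent(int(glyc.get('prediabetes', 0)), n)}%)")
print(f"hypertension:         {int(phen['hypertension'].sum())} ({percent(int(phen['hypertension'].sum()), n)}%)")
print(f"bariatric history:    {int(phen['bariatric_surgery'].sum())} ({percent(int(phen['bariatric_surgery'].sum()), n)}%)")
print(f"mean Charlson score:  {phen['charlson_score'].mean():.3f}")

# Percentages are prevalences among cohort members; pre-diabetes and
# diabetes are disjoint because the diabetes definition supersedes.
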