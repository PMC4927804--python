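"""Estimate neighborhood education and income for cohort members.

Each member's expected education (years) and income (dollars) is the mean
of the configured level values under their census block group's probability
profile; members without a geocode link are flagged instead of imputed.
"""

from ehrcohort import Config, SimulationConfig, build_cohort, default_sites, estimate_ses, generate_population

tables, _ = generate_population(SimulationConfig(seed=42, sites=default_sites(500, 8)))
cfg = Config(safety_net_sites=("dh_08",))
members, _ = build_cohort(tables, cfg)
ses = estimate_ses(members, tables.geocodes, tables.block_groups, cfg.education_values, cfg.income_values)

est = ses[ses["coverage"] == "estimated"]
print(f"members:                 {len(ses)}")
print(f"with geocode estimates:  {len(est)}")
print(f"without geocode:         {(ses['coverage'] == 'no_geocode').sum()}")
print(f"mean expected education: {est['expected_education'].mean():.2f} years")
print(f"mean expected income:    ${est['expected_income'].mean():,.0f}")

# Estimates are block-group expectations, not individual measurements:
# two members of the same block group always share the same values.
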