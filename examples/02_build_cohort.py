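"""Build the overweight/obesity cohort and print its attrition flow.

Exclusions are applied in a fixed order (membership -> age -> missing
height/weight -> pregnancy -> implausible values -> BMI < 23), each person
counted at the first step they fail, so the flow conserves counts exactly.
"""

from ehrcohort import Config, SimulationConfig, build_cohort, default_sites, flow_report, generate_population

tables, _ = generate_population(SimulationConfig(seed=42, sites=default_sites(500, 8)))
cfg = Config(safety_net_sites=("dh_08",))  # encounter-based eligibility for the safety-net site
members, flow = build_cohort(tables, cfg)

print(flow_report(flow).to_string(index=False))
print()
print(f"cohort members: {len(members)}, of which nested in 2009: {int(members['nested_2009'].sum())}")
print(members["bmi_category"].value_counts().to_string())

# The 'remaining' column is the running count after each exclusion; the last
# row is the cohort itself: adults with a plausible BMI of at least 23 kg/m2.
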