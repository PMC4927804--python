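"""Generate a seeded synthetic multi-site EHR population and inspect its manifest.

The generator plants eligibility failures, missing/implausible vitals,
pregnancy, BMI categories and phenotypes by construction, and its manifest
records the counts the downstream pipeline should recover exactly.
"""

from ehrcohort import SimulationConfig, default_sites, generate_population

tables, manifest = generate_population(SimulationConfig(seed=42, sites=default_sites(500, 8)))

print(f"persons generated:       {manifest['n_total']}")
print(f"entering members:        {manifest['entering_members']}")
for step in ("excluded_under18", "excluded_no_height_weight", "excluded_pregnant",
             "excluded_implausible", "excluded_bmi_below_threshold"):
    print(f"{step:32s} {manifest[step]}")
print(f"final cohort (planted):  {manifest['final_cohort']}")
print(f"vital records:           {len(tables.vitals)}")
print(f"diagnosis records:       {len(tables.diagnoses)}")

# The manifest is the ground truth the cohort builder is tested against:
# every person is attributed to the first eligibility step they fail.
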