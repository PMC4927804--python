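"""Draw the stratified health survey sample and compute response rates.

The design samples, per site, equal numbers from the overweight and obese
class 1 and 2 strata and twice as many from the pooled class 3+ stratum;
healthy-weight members are never sampled.  Response outcomes here are
simulated to show the response-rate arithmetic.
"""

import numpy as np
import pandas as pd

from ehrcohort import (
    Config,
    SimulationConfig,
    SurveyDesign,
    build_cohort,
    default_sites,
    generate_population,
    response_by_stratum,
    response_rate,
    sample_survey,
)

tables, _ = generate_population(SimulationConfig(seed=42, sites=default_sites(4200, 8)))
cfg = Config(safety_net_sites=("dh_08",))
members, _ = build_cohort(tables, cfg)

design = SurveyDesign(per_site_n=135, allocations={"overweight": 27, "obese1": 27, "obese2": 27, "obese3_plus": 54}, seed=42)
sampled = sample_survey(members, design)
print(f"sampled {len(sampled)} persons; per stratum:")
print(sampled["stratum"].value_counts().to_string())

# simulate outcomes: ~52% complete, 2% ineligible, rest refuse / no response
rng = np.random.default_rng(42)
status = rng.choice(["completed", "ineligible", "refused", "nonresponse"],
                    size=len(sampled), p=[0.52, 0.02, 0.17, 0.29])
outcomes = pd.DataFrame({"person_id": sampled["person_id"], "status": status,
                         "stratum": sampled["stratum"]})
print(f"\nresponse rate among eligible: {response_rate(outcomes)}%")
print(response_by_stratum(outcomes, "stratum").to_string(index=False))

# The response rate divides completed surveys by sampled-minus-ineligible;
# per-stratum percentages use each stratum's sampled n as denominator.
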