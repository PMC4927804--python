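import pytest
from hypothesis import HealthCheck, settings

import ehrcohort as ec
from ehrcohort.synth import SimulationConfig, default_sites, generate_population

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def pipeline_config() -> ec.Config:
    return ec.Config(safety_net_sites=("dh_08",))


@pytest.fixture(scope="session")
def small_population():
    """A seeded 1,200-person population across 7 insured sites + 1 safety-net."""
    cfg = SimulationConfig(seed=20, sites=default_sites(150, 8))
    tables, manifest = generate_population(cfg)
    return tables, manifest


@pytest.fixture(scope="session")
def small_cohort(small_population, pipeline_config):
    tables, _ = small_population
    members, flow = ec.build_cohort(tables, pipeline_config)
    return members, flow


@pytest.fixture(scope="session")
def small_phenotypes(small_population, small_cohort, pipeline_config):
    tables, _ = small_population
    members, _ = small_cohort
    return ec.phenotype_all(members, tables, pipeline_config)
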