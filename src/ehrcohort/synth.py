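"""Seeded multi-site synthetic EHR generator.

The generator plants every feature the pipeline must detect *by
construction*: a person flagged diabetic receives an event pattern that
satisfies the surveillance rule (an inpatient diagnosis, or two qualifying
events on distinct dates), a person flagged pregnant receives a
supervision-of-pregnancy code, a person flagged implausible receives a
vital drawn uniformly just outside the plausibility bounds, and so on.
Recovered prevalences and attrition counts are therefore a sharp test of
the rules engine rather than of any biophysical model.

Default parameters emulate a large insured adult population: ~22 % of
entering members under 18, ~20 % of adults without usable height/weight,
~2.8 % pregnancy among remaining adults, 0.11 % implausible vitals, ~15 %
of valid adults below the 23.0 kg/m² threshold, and marginal phenotype
prevalences of 29.49 % pre-diabetes, 14.98 % diabetes, 34.33 % hypertension
and 0.48 % bariatric history among final cohort members.  One site is a
safety-net system that records primary-care encounters instead of
enrollment spans.

The generator's manifest records, per person category, the realized counts
the pipeline should reproduce exactly (attrition steps, BMI categories,
phenotype positives among cohort members).
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .config import (
    BARIATRIC_CODES,
    BMI_CATEGORIES,
    BMI_CATEGORY_BOUNDS,
    EDUCATION_YEARS,
    INCOME_MIDPOINTS,
    PlausibilityBounds,
    StudyWindow,
)
from .schemas import TableSet

__all__ = ["SiteSpec", "MeasurementModel", "BmiBandMixture", "SimulationConfig", "generate_population", "default_sites"]

DEFAULT_RACE_MIX = {
    "white": 0.4902,
    "hispanic": 0.2289,
    "asian": 0.1040,
    "black": 0.1083,
    "native_hawaiian_pacific_islander": 0.0143,
    "american_indian_alaskan_native": 0.0055,
    "other_unknown": 0.0488,
}
DEFAULT_INSURANCE_MIX = {
    "private": 0.7481,
    "medicare": 0.2247,
    "medicaid_state_subsidized": 0.0258,
    "other_unknown": 0.0014,
}

HTN_CODES = ("401.0", "401.1", "401.9", "402.90", "403.91", "404.03", "405.99")
BACKGROUND_DX = ("460", "786.50", "719.46")  # never match any configured code list


def _check_probs(mapping: Mapping[str, float], what: str) -> None:
    for k, v in mapping.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{what}[{k!r}] = {v} outside [0, 1]")


@dataclass(frozen=True)
class SiteSpec:
    site_id: str
    n_persons: int
    safety_net: bool = False
    race_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RACE_MIX))
    insurance_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_INSURANCE_MIX))
    female_fraction: float = 0.517
    age_mean: float = 38.0
    age_sd: float = 23.0
    age_min: float = 0.0
    age_max: float = 95.0

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ValueError(f"site {self.site_id!r} has zero persons")
        _check_probs(self.race_mix, "race_mix")
        _check_probs(self.insurance_mix, "insurance_mix")
        for mix, name in ((self.race_mix, "race_mix"), (self.insurance_mix, "insurance_mix")):
            if abs(sum(mix.values()) - 1.0) > 1e-6:
                raise ValueError(f"{name} for site {self.site_id!r} does not sum to 1")


@dataclass(frozen=True)
class MeasurementModel:
    """Per-person probabilities of having usable anthropometric records."""

    p_weight_in_window: float = 0.78
    p_height_on_record: float = 0.85
    p_bmi_recorded: float = 0.40


@dataclass(frozen=True)
class BmiBandMixture:
    """Right-skewed adult BMI distribution as a mixture over category bands
    (band probability × uniform within the band)."""

    band_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "below_threshold": 0.1488,
            "healthy": 0.1735,
            "overweight": 0.3439,
            "obese1": 0.1939,
            "obese2": 0.0839,
            "obese3": 0.0476,
            "obese4": 0.0084,
        }
    )
    band_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "below_threshold": (17.0, 23.0),
            "healthy": (23.0, 25.0),
            "overweight": (25.0, 30.0),
            "obese1": (30.0, 35.0),
            "obese2": (35.0, 40.0),
            "obese3": (40.0, 50.0),
            "obese4": (50.0, 60.0),
        }
    )

    def __post_init__(self) -> None:
        _check_probs(self.band_probs, "band_probs")
        if abs(sum(self.band_probs.values()) - 1.0) > 1e-9:
            raise ValueError("BMI band mixture weights must sum to 1")


def default_sites(n_per_site: int = 1000, n_sites: int = 8) -> tuple[SiteSpec, ...]:
    """Seven enrollment-based sites plus one safety-net site (the last)."""
    sites = [SiteSpec(f"kp_{i:02d}", n_per_site) for i in range(1, n_sites)]
    sites.append(SiteSpec(f"dh_{n_sites:02d}", n_per_site, safety_net=True))
    return tuple(sites)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    sites: tuple[SiteSpec, ...] = field(default_factory=default_sites)
    bmi_model: BmiBandMixture = field(default_factory=BmiBandMixture)
    measurement: MeasurementModel = field(default_factory=MeasurementModel)
    implausible_rate: float = 0.0011
    pregnancy_rate: float = 0.09  # among women aged 18-49
    enrollment_gap_rate: float = 0.05
    lab_testing_rate: Mapping[str, float] = field(
        default_factory=lambda: {
            "hba1c": 0.40,
            "fasting_glucose": 0.50,
            "random_glucose": 0.30,
            "ogtt_2h": 0.02,
        }
    )
    phenotype_prevalences: Mapping[str, float] = field(
        default_factory=lambda: {
            "prediabetes": 0.2949,
            "diabetes": 0.1498,
            "hypertension": 0.3433,
            "bariatric": 0.0048,
        }
    )
    charlson_condition_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "chronic_pulmonary": 0.08,
            "congestive_heart_failure": 0.04,
            "malignancy": 0.04,
            "renal": 0.03,
            "cerebrovascular": 0.03,
            "mild_liver": 0.01,
        }
    )
    #: representative planted code per Charlson condition
    charlson_codes: Mapping[str, str] = field(
        default_factory=lambda: {
            "chronic_pulmonary": "493.90",
            "congestive_heart_failure": "428.0",
            "malignancy": "174.9",
            "renal": "585.6",
            "cerebrovascular": "434.91",
            "mild_liver": "571.5",
        }
    )
    nested_2009_rate: float = 0.60
    geocode_rate: float = 0.95
    n_block_groups: int = 30
    duplicate_vital_rate: float = 0.15
    background_dx_rate: float = 0.30
    window: StudyWindow = field(default_factory=StudyWindow)
    bounds: PlausibilityBounds = field(default_factory=PlausibilityBounds)

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("at least one site is required")
        _check_probs(self.lab_testing_rate, "lab_testing_rate")
        _check_probs(self.phenotype_prevalences, "phenotype_prevalences")
        _check_probs(self.charlson_condition_rates, "charlson_condition_rates")
        for name in ("implausible_rate", "pregnancy_rate", "enrollment_gap_rate",
                     "nested_2009_rate", "geocode_rate", "duplicate_vital_rate",
                     "background_dx_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        p = self.phenotype_prevalences
        if p.get("diabetes", 0) + p.get("prediabetes", 0) > 1.0:
            raise ValueError("diabetes + prediabetes prevalence targets exceed 1")


class _Emitter:
    """Accumulates rows for every output table."""

    def __init__(self) -> None:
        self.persons: list = []
        self.enrollment: list = []
        self.vitals: list = []
        self.labs: list = []
        self.diagnoses: list = []
        self.procedures: list = []
        self.dispenses: list = []
        self.encounters: list = []
        self.geocodes: list = []
        self.pregnancy: list = []
        self.seq = 0

    def vital(self, pid: str, d: dt.date, kind: str, value: float) -> None:
        self.seq += 1
        self.vitals.append((pid, d, kind, float(value), self.seq))


def _categorize(bmi: float) -> str:
    if bmi < BMI_CATEGORY_BOUNDS[0]:
        return "below_threshold"
    idx = int(np.searchsorted(BMI_CATEGORY_BOUNDS, bmi, side="right"))
    return BMI_CATEGORIES[idx - 1]


def _bariatric_system(code: str) -> str:
    if "." in code:
        return "icd9_proc"
    if code.startswith("S"):
        return "hcpcs"
    return "cpt4"


def generate_population(config: SimulationConfig) -> tuple[TableSet, dict]:
    """Generate the full table set plus a manifest of realized counts.

    Deterministic given ``config`` (including its seed): the same
    configuration always yields byte-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    window, bounds = config.window, config.bounds
    n_days = (window.end - window.start).days + 1
    ref = window.age_reference_date
    em = _Emitter()
    run_log: list[str] = []

    def win_day(offset: int) -> dt.date:
        return window.start + dt.timedelta(days=int(offset))

    def rand_win_date() -> dt.date:
        return win_day(rng.integers(0, n_days))

    manifest: dict = {
        "n_total": 0,
        "entering_members": 0,
        "excluded_under18": 0,
        "excluded_no_height_weight": 0,
        "excluded_pregnant": 0,
        "excluded_implausible": 0,
        "excluded_bmi_below_threshold": 0,
        "final_cohort": 0,
        "nested_2009": 0,
        "category_counts": {c: 0 for c in BMI_CATEGORIES},
        "phenotype_counts": {"diabetes": 0, "prediabetes": 0, "hypertension": 0, "bariatric": 0},
        "sites": {},
        "run_log": run_log,
    }

    bg_ids = [f"bg_{i:03d}" for i in range(config.n_block_groups)]
    prev = config.phenotype_prevalences
    p_dm = prev.get("diabetes", 0.0)
    p_pre = prev.get("prediabetes", 0.0)
    glyc_p = np.array([p_dm, p_pre, 1.0 - p_dm - p_pre])
    bands = list(config.bmi_model.band_probs)
    band_p = np.array([config.bmi_model.band_probs[b] for b in bands])
    bariatric_codes = sorted(BARIATRIC_CODES)

    for site in config.sites:
        n = site.n_persons
        site_stats = {"final": 0, "categories": {c: 0 for c in BMI_CATEGORIES}}
        manifest["sites"][site.site_id] = site_stats
        races = list(site.race_mix)
        race_p = np.array([site.race_mix[r] for r in races])
        insurances = list(site.insurance_mix)
        ins_p = np.array([site.insurance_mix[i] for i in insurances])

        ages = np.clip(rng.normal(site.age_mean, site.age_sd, n), site.age_min, site.age_max)
        ages = np.floor(ages).astype(int)
        female = rng.random(n) < site.female_fraction
        race_idx = rng.choice(len(races), n, p=race_p / race_p.sum())
        ins_idx = rng.choice(len(insurances), n, p=ins_p / ins_p.sum())
        membership_fail = rng.random(n) < config.enrollment_gap_rate
        has_w = rng.random(n) < config.measurement.p_weight_in_window
        has_h = rng.random(n) < config.measurement.p_height_on_record
        has_b = rng.random(n) < config.measurement.p_bmi_recorded
        implaus = rng.random(n) < config.implausible_rate
        preg_draw = rng.random(n) < config.pregnancy_rate
        band_idx = rng.choice(len(bands), n, p=band_p)
        glyc_idx = rng.choice(3, n, p=glyc_p)
        htn = rng.random(n) < prev.get("hypertension", 0.0)
        bari = rng.random(n) < prev.get("bariatric", 0.0)
        nested = rng.random(n) < config.nested_2009_rate
        geocoded = rng.random(n) < config.geocode_rate

        for i in range(n):
            pid = f"{site.site_id}-{i:06d}"
            manifest["n_total"] += 1
            age = int(ages[i])
            # birth date placing the person at exactly `age` completed years
            anchor = dt.date(ref.year - age, ref.month, ref.day)
            birth = anchor - dt.timedelta(days=int(rng.integers(0, 365)))
            sex = "female" if female[i] else "male"
            em.persons.append((pid, birth, sex, races[race_idx[i]], site.site_id, insurances[ins_idx[i]]))

            pregnant = bool(preg_draw[i]) and sex == "female" and 18 <= age <= 49
            em.pregnancy.append((pid, pregnant))
            if pregnant:
                em.diagnoses.append((pid, rand_win_date(), "V22.1", "outpatient"))

            # --- membership / encounters -----------------------------------
            if site.safety_net:
                if membership_fail[i]:
                    if rng.random() < 0.5:
                        em.encounters.append((pid, dt.date(2011, 6, 15), "primary_care"))
                    if rng.random() < 0.5:
                        em.encounters.append((pid, rand_win_date(), "other"))
                else:
                    for _ in range(int(rng.integers(1, 4))):
                        em.encounters.append((pid, rand_win_date(), "primary_care"))
            elif membership_fail[i]:
                if rng.random() < 0.7:  # gapped spans, neither covering 12 months
                    l1 = int(rng.integers(60, 301))
                    l2 = int(rng.integers(60, 301))
                    em.enrollment.append((pid, window.start, win_day(l1 - 1)))
                    em.enrollment.append((pid, win_day(n_days - l2), window.end))
            else:
                if nested[i]:
                    start = dt.date(2009, 1, 1) + dt.timedelta(days=int(rng.integers(0, 365)))
                    end = window.start + dt.timedelta(days=int(rng.integers(364, n_days)))
                else:
                    length = int(rng.integers(window.min_continuous_days, n_days + 1))
                    s = int(rng.integers(0, n_days - length + 1))
                    start = win_day(s) - dt.timedelta(days=int(rng.integers(0, 400)))
                    start = max(start, dt.date(2010, 1, 1))
                    end = win_day(s + length - 1)
                if rng.random() < 0.2:  # split into two adjacent spans (merge exercise)
                    mid = start + (end - start) / 2
                    em.enrollment.append((pid, start, mid))
                    em.enrollment.append((pid, mid + dt.timedelta(days=1), end))
                else:
                    em.enrollment.append((pid, start, end))

            # --- anthropometrics -------------------------------------------
            bmi = float(rng.uniform(*config.bmi_model.band_ranges[bands[band_idx[i]]]))
            height = float(np.clip(rng.normal(1.70, 0.10), 1.35, 2.20))
            height_date = dt.date(2008, 1, 1) + dt.timedelta(days=int(rng.integers(0, 2160)))
            resolved: float | None = None
            if implaus[i]:
                variant = ("weight", "height", "bmi")[int(rng.integers(0, 3))]
                low = rng.random() < 0.5
                if variant == "weight":
                    em.vital(pid, height_date, "height", height)
                    value = rng.uniform(5.0, bounds.weight_min_kg) if low else rng.uniform(bounds.weight_max_kg, 500.0)
                    em.vital(pid, rand_win_date(), "weight", value)
                elif variant == "height":
                    value = rng.uniform(0.90, bounds.height_min_m) if low else rng.uniform(bounds.height_max_m, 2.60)
                    em.vital(pid, height_date, "height", value)
                    em.vital(pid, rand_win_date(), "weight", bmi * 1.70**2)
                else:
                    value = rng.uniform(2.0, bounds.bmi_min) if low else rng.uniform(bounds.bmi_max, 95.0)
                    em.vital(pid, rand_win_date(), "bmi", value)
            else:
                weight = bmi * height * height
                wdate = rand_win_date()
                if has_w[i]:
                    if rng.random() < config.duplicate_vital_rate:
                        # decoy weights: an earlier date and a same-day lower ordinal
                        em.vital(pid, window.start + dt.timedelta(days=int(rng.integers(0, max(1, (wdate - window.start).days)))), "weight", weight * 1.1)
                        em.vital(pid, wdate, "weight", weight * 0.9)
                    em.vital(pid, wdate, "weight", weight)
                if has_h[i]:
                    em.vital(pid, height_date, "height", height)
                if has_b[i]:
                    em.vital(pid, rand_win_date(), "bmi", bmi)
                if has_b[i]:
                    resolved = bmi
                elif has_w[i] and has_h[i]:
                    resolved = weight / (height * height)

            # --- planted phenotypes ----------------------------------------
            glyc = ("diabetes", "prediabetes", "none")[glyc_idx[i]]
            if glyc == "diabetes":
                if rng.random() < 0.3:
                    em.diagnoses.append((pid, rand_win_date(), f"250.{rng.integers(0, 10)}0", "inpatient"))
                else:
                    d1, d2 = (win_day(o) for o in sorted(rng.choice(n_days, 2, replace=False)))
                    for d in (d1, d2):
                        kind = int(rng.integers(0, 3))
                        if kind == 0:
                            em.diagnoses.append((pid, d, "250.00", "outpatient"))
                        elif kind == 1:
                            em.dispenses.append((pid, d, "anti_hyperglycemic"))
                        else:
                            lab = int(rng.integers(0, 3))
                            if lab == 0:
                                em.labs.append((pid, d, "hba1c", float(rng.uniform(6.5, 9.5))))
                            elif lab == 1:
                                em.labs.append((pid, d, "fasting_glucose", float(rng.uniform(126.0, 200.0))))
                            else:
                                em.labs.append((pid, d, "random_glucose", float(rng.uniform(200.0, 300.0))))
            elif glyc == "prediabetes":
                mech = int(rng.integers(0, 4))
                d = rand_win_date()
                if mech == 0:
                    em.labs.append((pid, d, "hba1c", float(rng.uniform(5.7, 6.4))))
                elif mech == 1:
                    em.labs.append((pid, d, "fasting_glucose", float(rng.uniform(100.0, 125.0))))
                elif mech == 2:
                    em.labs.append((pid, d, "ogtt_2h", float(rng.uniform(140.0, 199.0))))
                else:
                    code = ("790.2", "790.29", "790.21", "790.22")[int(rng.integers(0, 4))]
                    em.diagnoses.append((pid, d, code, "outpatient"))
            if htn[i]:
                if rng.random() < 0.2:
                    em.diagnoses.append((pid, rand_win_date(), HTN_CODES[int(rng.integers(0, len(HTN_CODES)))], "inpatient"))
                else:
                    d1, d2 = (win_day(o) for o in sorted(rng.choice(n_days, 2, replace=False)))
                    for d in (d1, d2):
                        em.diagnoses.append((pid, d, HTN_CODES[int(rng.integers(0, len(HTN_CODES)))], "outpatient"))
            if bari[i]:
                code = bariatric_codes[int(rng.integers(0, len(bariatric_codes)))]
                pdate = dt.date(2009, 1, 1) + dt.timedelta(days=int(rng.integers(0, 1826)))
                em.procedures.append((pid, pdate, code, _bariatric_system(code)))
            for cond, rate in config.charlson_condition_rates.items():
                if rng.random() < rate:
                    em.diagnoses.append((pid, rand_win_date(), config.charlson_codes[cond], "outpatient"))

            # background noise: innocuous diagnoses and normal-range labs
            if rng.random() < config.background_dx_rate:
                em.diagnoses.append((pid, rand_win_date(), BACKGROUND_DX[int(rng.integers(0, len(BACKGROUND_DX)))], "outpatient"))
            for test, rate in config.lab_testing_rate.items():
                if rng.random() < rate:
                    lo, hi = {"hba1c": (4.8, 5.6), "fasting_glucose": (75.0, 99.0),
                              "random_glucose": (70.0, 139.0), "ogtt_2h": (90.0, 139.0)}[test]
                    em.labs.append((pid, rand_win_date(), test, float(rng.uniform(lo, hi))))

            if geocoded[i]:
                em.geocodes.append((pid, bg_ids[int(rng.integers(0, len(bg_ids)))]))

            # --- manifest: first-failing-step attribution -------------------
            if membership_fail[i]:
                continue
            manifest["entering_members"] += 1
            if age < 18:
                manifest["excluded_under18"] += 1
                continue
            if resolved is None and not implaus[i]:
                manifest["excluded_no_height_weight"] += 1
                continue
            if pregnant:
                manifest["excluded_pregnant"] += 1
                continue
            if implaus[i]:
                manifest["excluded_implausible"] += 1
                continue
            assert resolved is not None
            if resolved < BMI_CATEGORY_BOUNDS[0]:
                manifest["excluded_bmi_below_threshold"] += 1
                continue
            cat = _categorize(resolved)
            manifest["final_cohort"] += 1
            manifest["category_counts"][cat] += 1
            site_stats["final"] += 1
            site_stats["categories"][cat] += 1
            if nested[i] and not site.safety_net:
                manifest["nested_2009"] += 1
            if glyc != "none":
                manifest["phenotype_counts"][glyc] += 1
            if htn[i]:
                manifest["phenotype_counts"]["hypertension"] += 1
            if bari[i]:
                manifest["phenotype_counts"]["bariatric"] += 1

    # block-group profiles: Dirichlet probabilities per domain
    bg_rows = []
    for bg in bg_ids:
        for domain, levels in (("education", list(EDUCATION_YEARS)), ("income", list(INCOME_MIDPOINTS))):
            probs = rng.dirichlet(np.ones(len(levels)))
            probs[-1] = 1.0 - probs[:-1].sum()
            for level, p in zip(levels, probs):
                bg_rows.append((bg, domain, level, float(p)))

    feasible_pct = 100.0 * manifest["final_cohort"] / max(1, manifest["entering_members"])
    run_log.append(
        f"{manifest['final_cohort']} of {manifest['entering_members']} entering members "
        f"({feasible_pct:.2f}%) reach the final cohort"
    )

    def frame(rows, cols, date_cols):
        df = pd.DataFrame(rows, columns=cols)
        for c in date_cols:
            df[c] = pd.to_datetime(df[c])
        return df

    tables = TableSet(
        persons=frame(em.persons, ["person_id", "birth_date", "sex", "race_ethnicity", "site_id", "insurance"], ["birth_date"]),
        enrollment=frame(em.enrollment, ["person_id", "start_date", "end_date"], ["start_date", "end_date"]),
        vitals=frame(em.vitals, ["person_id", "measure_date", "kind", "value", "record_seq"], ["measure_date"]),
        labs=frame(em.labs, ["person_id", "result_date", "test", "value"], ["result_date"]),
        diagnoses=frame(em.diagnoses, ["person_id", "dx_date", "code", "setting"], ["dx_date"]),
        procedures=frame(em.procedures, ["person_id", "px_date", "code", "code_system"], ["px_date"]),
        dispenses=frame(em.dispenses, ["person_id", "dispense_date", "drug_class"], ["dispense_date"]),
        encounters=frame(em.encounters, ["person_id", "encounter_date", "encounter_type"], ["encounter_date"]),
        geocodes=pd.DataFrame(em.geocodes, columns=["person_id", "block_group_id"]),
        block_groups=pd.DataFrame(bg_rows, columns=["block_group_id", "domain", "level", "probability"]),
        pregnancy=pd.DataFrame(em.pregnancy, columns=["person_id", "pregnant_in_window"]),
    )
    return tables, manifest
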