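"""Study configuration: window, plausibility bounds, BMI categories, code lists.

Everything a site analyst might need to change — the study window, the
glycemic thresholds, the diagnosis/procedure code lists, the comorbidity
map, the survey design — is data held here, loadable from YAML, never
hard-coded inside the pipeline stages.

Defaults encode the study conditions: a 2012–2013 cross-sectional window,
age referenced to the window end, WHO Asian-aware BMI cut points starting
the cohort at 23.0 kg/m², and plausibility bounds of [4 ft, 8 ft) for
height, [50 lb, 1000 lb) for weight and [5, 90) kg/m² for BMI (stated
imperial limits converted once, exactly, to canonical units).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import yaml

from .schemas import FT_TO_M, LB_TO_KG

__all__ = [
    "StudyWindow",
    "PlausibilityBounds",
    "BMI_CATEGORY_BOUNDS",
    "BMI_CATEGORIES",
    "GlycemicThresholds",
    "CharlsonCondition",
    "CharlsonMap",
    "default_charlson_map",
    "SurveyDesign",
    "STRATUM_OF_CATEGORY",
    "Config",
    "load_config",
    "HYPERTENSION_PREFIXES",
    "PREGNANCY_PREFIXES",
    "BARIATRIC_CODES",
    "BARIATRIC_LOOKBACK",
    "EDUCATION_YEARS",
    "INCOME_MIDPOINTS",
]


@dataclass(frozen=True)
class StudyWindow:
    """Closed calendar-date window over which eligibility and events are assessed."""

    start: dt.date = dt.date(2012, 1, 1)
    end: dt.date = dt.date(2013, 12, 31)
    age_reference_date: dt.date = dt.date(2013, 12, 31)
    min_continuous_days: int = 365

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("study window start must precede end")
        if not (self.start <= self.age_reference_date <= self.end):
            raise ValueError("age reference date must lie within the study window")

    def contains(self, d: dt.date) -> bool:
        return self.start <= d <= self.end


@dataclass(frozen=True)
class PlausibilityBounds:
    """Half-open plausible ranges [min, max) for canonical-unit vitals."""

    height_min_m: float = 4 * FT_TO_M  # 1.2192
    height_max_m: float = 8 * FT_TO_M  # 2.4384
    weight_min_kg: float = 50 * LB_TO_KG  # 22.6796185
    weight_max_kg: float = 1000 * LB_TO_KG  # 453.59237
    bmi_min: float = 5.0
    bmi_max: float = 90.0

    def __post_init__(self) -> None:
        for lo, hi in (
            (self.height_min_m, self.height_max_m),
            (self.weight_min_kg, self.weight_max_kg),
            (self.bmi_min, self.bmi_max),
        ):
            if not lo < hi:
                raise ValueError("plausibility bounds must satisfy min < max")


#: Left edges of the half-open BMI category partition of [23, 90); values
#: below 23.0 fall in ``below_threshold``.  The healthy band starts at 23.0
#: (not 25.0) to accommodate the WHO Asian overweight cut point.
BMI_CATEGORY_BOUNDS: tuple[float, ...] = (23.0, 25.0, 30.0, 35.0, 40.0, 50.0)
BMI_CATEGORIES: tuple[str, ...] = (
    "healthy",
    "overweight",
    "obese1",
    "obese2",
    "obese3",
    "obese4",
)

HYPERTENSION_PREFIXES: tuple[str, ...] = ("401", "402", "403", "404", "405")

#: Pregnancy is not given an explicit mechanism in the source cohort
#: definition; by default it is derived from ICD-9 supervision-of-pregnancy
#: and obstetric-chapter codes on 2012–2013 diagnoses.  A precomputed
#: pregnancy table, when present, takes precedence.
PREGNANCY_PREFIXES: tuple[str, ...] = ("V22", "V23") + tuple(str(c) for c in range(630, 680))

#: Bariatric-surgery procedure codes (CPT-4 / HCPCS / ICD-9 procedure),
#: matched exactly, searched over a 2009–2013 lookback.
BARIATRIC_CODES: frozenset[str] = frozenset(
    {
        "43842",
        "43843",
        "43846",
        "43847",
        "43659",
        "43621",
        "43633",
        "43.82",
        "43.89",
        "44.31",
        "44.38",
        "44.39",
        "44.68",
        "44.69",
        "44.95",
        "43644",
        "43645",
        "43770",
        "43775",
        "43844",
        "43845",
        "S2082",
        "S2085",
    }
)
BARIATRIC_LOOKBACK: tuple[dt.date, dt.date] = (dt.date(2009, 1, 1), dt.date(2013, 12, 31))


@dataclass(frozen=True)
class GlycemicThresholds:
    """ADA-style glycemic bands; pre-diabetes bands inclusive on both ends,
    diabetes thresholds inclusive ("equal or greater")."""

    hba1c_pre: tuple[float, float] = (5.7, 6.4)  # %
    fpg_pre: tuple[float, float] = (100.0, 125.0)  # mg/dL
    ogtt_pre: tuple[float, float] = (140.0, 199.0)  # mg/dL, 2-h post-load
    hba1c_dm: float = 6.5
    fpg_dm: float = 126.0
    rpg_dm: float = 200.0
    pre_dx_codes: tuple[str, ...] = ("790.2", "790.29", "790.21", "790.22")
    dm_dx_prefixes: tuple[str, ...] = ("250",)

    def __post_init__(self) -> None:
        if not (
            self.hba1c_pre[1] < self.hba1c_dm
            and self.fpg_pre[1] < self.fpg_dm
            and self.ogtt_pre[1] <= self.rpg_dm
        ):
            raise ValueError("pre-diabetes bands must lie below diabetes thresholds")


@dataclass(frozen=True)
class CharlsonCondition:
    name: str
    prefixes: tuple[str, ...]
    weight: int


@dataclass(frozen=True)
class CharlsonMap:
    """Weighted comorbidity map with hierarchy pairs (superior, inferior):
    when the superior (e.g. complicated) form is present the inferior form
    contributes nothing, so each hierarchy adds one weight at most."""

    conditions: tuple[CharlsonCondition, ...]
    hierarchies: tuple[tuple[str, str], ...] = ()
    window: StudyWindow = field(default_factory=StudyWindow)

    def __post_init__(self) -> None:
        names = [c.name for c in self.conditions]
        if len(names) != len(set(names)):
            raise ValueError("Charlson condition names must be unique")
        if any(c.weight < 1 for c in self.conditions):
            raise ValueError("Charlson weights must be >= 1")
        known = set(names)
        for sup, inf in self.hierarchies:
            if sup not in known or inf not in known:
                raise ValueError(f"hierarchy pair ({sup!r}, {inf!r}) names unknown condition")

    def condition(self, name: str) -> CharlsonCondition:
        return next(c for c in self.conditions if c.name == name)


def default_charlson_map(window: StudyWindow | None = None) -> CharlsonMap:
    """Classic 17-condition Deyo ICD-9-CM weighting (condensed prefixes).

    The map is configuration data: sites using an extended condition list
    supply their own :class:`CharlsonMap` with the same structure.
    """
    c = CharlsonCondition
    conditions = (
        c("myocardial_infarction", ("410", "412"), 1),
        c("congestive_heart_failure", ("428",), 1),
        c("peripheral_vascular", ("441", "443.9", "785.4", "V43.4"), 1),
        c("cerebrovascular", tuple(str(x) for x in range(430, 439)), 1),
        c("dementia", ("290",), 1),
        c("chronic_pulmonary", tuple(str(x) for x in range(490, 497)) + tuple(str(x) for x in range(500, 506)) + ("506.4",), 1),
        c("rheumatic", ("710.0", "710.1", "710.4", "714.0", "714.1", "714.2", "714.81", "725"), 1),
        c("peptic_ulcer", ("531", "532", "533", "534"), 1),
        c("mild_liver", ("571.2", "571.4", "571.5", "571.6"), 1),
        c("diabetes", ("250.0", "250.1", "250.2", "250.3", "250.7"), 1),
        c("diabetes_complicated", ("250.4", "250.5", "250.6"), 2),
        c("hemiplegia", ("342", "344.1"), 2),
        c("renal", ("582", "583.0", "583.1", "583.2", "583.4", "583.6", "583.7", "585", "586", "588"), 2),
        c(
            "malignancy",
            tuple(str(x) for x in range(140, 173))
            + tuple(str(x) for x in range(174, 196))
            + tuple(str(x) for x in range(200, 209)),
            2,
        ),
        c("moderate_severe_liver", ("572.2", "572.3", "572.4", "572.8", "456.0", "456.1", "456.2"), 3),
        c("metastatic", ("196", "197", "198", "199.0", "199.1"), 6),
        c("aids", ("042", "043", "044"), 6),
    )
    hierarchies = (
        ("diabetes_complicated", "diabetes"),
        ("moderate_severe_liver", "mild_liver"),
        ("metastatic", "malignancy"),
    )
    return CharlsonMap(conditions, hierarchies, window or StudyWindow())


#: Survey stratum for each cohort BMI category; healthy-weight members are
#: never sampled, and obese classes 3 and 4 are pooled at sampling time.
STRATUM_OF_CATEGORY: Mapping[str, str | None] = {
    "healthy": None,
    "overweight": "overweight",
    "obese1": "obese1",
    "obese2": "obese2",
    "obese3": "obese3_plus",
    "obese4": "obese3_plus",
}


@dataclass(frozen=True)
class SurveyDesign:
    """Stratified survey design: per-site allocations by BMI stratum."""

    per_site_n: int = 675
    allocations: Mapping[str, int] = field(
        default_factory=lambda: {
            "overweight": 135,
            "obese1": 135,
            "obese2": 135,
            "obese3_plus": 270,
        }
    )
    sites: tuple[str, ...] | None = None  # None: every site present in the cohort
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.allocations.values()):
            raise ValueError("stratum allocations must be >= 0")
        if sum(self.allocations.values()) != self.per_site_n:
            raise ValueError("stratum allocations must sum to per_site_n")


#: Default numeric values per 2010-census-style attainment / income band.
EDUCATION_YEARS: Mapping[str, float] = {
    "less_than_hs": 10.0,
    "hs_grad": 12.0,
    "some_college": 14.0,
    "bachelors": 16.0,
    "graduate": 18.0,
}
INCOME_MIDPOINTS: Mapping[str, float] = {
    "lt_25k": 12_500.0,
    "25_50k": 37_500.0,
    "50_75k": 62_500.0,
    "75_100k": 87_500.0,
    "100_150k": 125_000.0,
    "gt_150k": 175_000.0,
}


@dataclass(frozen=True)
class Config:
    """Top-level pipeline configuration bundle."""

    window: StudyWindow = field(default_factory=StudyWindow)
    bounds: PlausibilityBounds = field(default_factory=PlausibilityBounds)
    glycemic: GlycemicThresholds = field(default_factory=GlycemicThresholds)
    hypertension_prefixes: tuple[str, ...] = HYPERTENSION_PREFIXES
    pregnancy_prefixes: tuple[str, ...] = PREGNANCY_PREFIXES
    bariatric_codes: frozenset[str] = BARIATRIC_CODES
    bariatric_lookback: tuple[dt.date, dt.date] = BARIATRIC_LOOKBACK
    charlson: CharlsonMap = field(default_factory=default_charlson_map)
    survey: SurveyDesign = field(default_factory=SurveyDesign)
    education_values: Mapping[str, float] = field(default_factory=lambda: dict(EDUCATION_YEARS))
    income_values: Mapping[str, float] = field(default_factory=lambda: dict(INCOME_MIDPOINTS))
    safety_net_sites: tuple[str, ...] = ()
    gap_tolerance_days: int = 0
    #: require the two "other" diabetes events (and the two outpatient
    #: hypertension codes) to fall on distinct calendar dates
    distinct_dates_required: bool = True


def _date(v) -> dt.date:
    return v if isinstance(v, dt.date) else dt.date.fromisoformat(str(v))


def load_config(path) -> Config:
    """Load a YAML config file, overriding defaults field by field."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = Config()
    if "window" in raw:
        w = raw["window"]
        cfg = replace(
            cfg,
            window=StudyWindow(
                start=_date(w.get("start", cfg.window.start)),
                end=_date(w.get("end", cfg.window.end)),
                age_reference_date=_date(w.get("age_reference_date", w.get("end", cfg.window.age_reference_date))),
                min_continuous_days=int(w.get("min_continuous_days", cfg.window.min_continuous_days)),
            ),
        )
        # the comorbidity evaluation window follows the study window unless
        # an explicit charlson block overrides it below
        cfg = replace(cfg, charlson=default_charlson_map(cfg.window))
    if "bounds" in raw:
        cfg = replace(cfg, bounds=PlausibilityBounds(**raw["bounds"]))
    if "glycemic" in raw:
        g = dict(raw["glycemic"])
        for k in ("hba1c_pre", "fpg_pre", "ogtt_pre"):
            if k in g:
                g[k] = tuple(g[k])
        for k in ("pre_dx_codes", "dm_dx_prefixes"):
            if k in g:
                g[k] = tuple(str(x) for x in g[k])
        cfg = replace(cfg, glycemic=GlycemicThresholds(**g))
    if "hypertension_prefixes" in raw:
        cfg = replace(cfg, hypertension_prefixes=tuple(str(x) for x in raw["hypertension_prefixes"]))
    if "pregnancy_prefixes" in raw:
        cfg = replace(cfg, pregnancy_prefixes=tuple(str(x) for x in raw["pregnancy_prefixes"]))
    if "bariatric_codes" in raw:
        cfg = replace(cfg, bariatric_codes=frozenset(str(x) for x in raw["bariatric_codes"]))
    if "bariatric_lookback" in raw:
        lo, hi = raw["bariatric_lookback"]
        cfg = replace(cfg, bariatric_lookback=(_date(lo), _date(hi)))
    if "charlson" in raw:
        entries = tuple(
            CharlsonCondition(e["name"], tuple(str(p) for p in e["prefixes"]), int(e["weight"]))
            for e in raw["charlson"].get("conditions", [])
        )
        hier = tuple((a, b) for a, b in raw["charlson"].get("hierarchies", []))
        cfg = replace(cfg, charlson=CharlsonMap(entries, hier, cfg.window))
    if "survey" in raw:
        s = raw["survey"]
        cfg = replace(
            cfg,
            survey=SurveyDesign(
                per_site_n=int(s.get("per_site_n", 675)),
                allocations=dict(s.get("allocations", Config().survey.allocations)),
                sites=tuple(s["sites"]) if s.get("sites") else None,
                seed=int(s.get("seed", 0)),
            ),
        )
    for key in ("safety_net_sites",):
        if key in raw:
            cfg = replace(cfg, **{key: tuple(raw[key])})
    for key in ("gap_tolerance_days", "distinct_dates_required"):
        if key in raw:
            cfg = replace(cfg, **{key: raw[key]})
    if "education_values" in raw:
        cfg = replace(cfg, education_values={str(k): float(v) for k, v in raw["education_values"].items()})
    if "income_values" in raw:
        cfg = replace(cfg, income_values={str(k): float(v) for k, v in raw["income_values"].items()})
    return cfg
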