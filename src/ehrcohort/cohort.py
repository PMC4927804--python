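"""Cohort eligibility, anthropometric plausibility and BMI classification.

The pipeline applies exclusions in a fixed order, attributing each person to
the *first* step they fail, so the attrition flow satisfies exact count
conservation:

1. membership eligibility — ≥ 12 months of continuous (gap-merged)
   enrollment intersecting the 2012–2013 window, or, for safety-net sites
   that do not enroll members, ≥ 1 primary-care encounter in the window;
2. age — at least 18 completed years on the reference date;
3. missing anthropometrics — no in-window recorded BMI and no
   (in-window weight + height on record);
4. pregnancy during the window;
5. implausible values — after removing out-of-bounds vitals no plausible
   BMI can be resolved (or the computed BMI itself falls outside [5, 90));
6. BMI below the 23.0 kg/m² cohort threshold.

Heights are searched over the person's full record; weights and recorded
BMIs only within the window; ties on date are broken by ingestion ordinal.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import (
    BMI_CATEGORIES,
    BMI_CATEGORY_BOUNDS,
    Config,
    PlausibilityBounds,
    StudyWindow,
)
from .schemas import TableSet, VitalRecord, match_mask

__all__ = [
    "CohortFlow",
    "continuous_enrollment_ok",
    "eligible_safety_net",
    "age_at",
    "latest_vital",
    "compute_bmi",
    "plausible",
    "classify_bmi",
    "resolve_person_bmi",
    "build_cohort",
]

EXCLUSION_STEPS = (
    "excluded_under18",
    "excluded_no_height_weight",
    "excluded_pregnant",
    "excluded_implausible",
    "excluded_bmi_below_threshold",
)


@dataclass(frozen=True)
class CohortFlow:
    """Ordered attrition accounting from eligible members to the final cohort."""

    entering_members: int
    excluded_under18: int
    excluded_no_height_weight: int
    excluded_pregnant: int
    excluded_implausible: int
    excluded_bmi_below_threshold: int
    final_cohort: int

    @property
    def adults_remaining(self) -> int:
        """Count after the plausibility filter, before the BMI threshold."""
        return self.entering_members - (
            self.excluded_under18
            + self.excluded_no_height_weight
            + self.excluded_pregnant
            + self.excluded_implausible
        )

    def exclusions(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in EXCLUSION_STEPS}

    @property
    def conserved(self) -> bool:
        return self.entering_members - sum(self.exclusions().values()) == self.final_cohort


def continuous_enrollment_ok(
    spans: Sequence, window: StudyWindow, gap_tolerance_days: int = 0
) -> bool:
    """True iff, after merging spans separated by ≤ ``gap_tolerance_days``
    uncovered days, some merged span covers ≥ ``window.min_continuous_days``
    days inside the window (closed interval day counting)."""
    periods = sorted((s.start_date, s.end_date) for s in spans)
    if not periods:
        return False
    merged: list[list[dt.date]] = [list(periods[0])]
    for start, end in periods[1:]:
        gap = (start - merged[-1][1]).days - 1
        if gap <= gap_tolerance_days:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    for start, end in merged:
        lo, hi = max(start, window.start), min(end, window.end)
        if (hi - lo).days + 1 >= window.min_continuous_days:
            return True
    return False


def eligible_safety_net(encounter_dates: Iterable[dt.date], window: StudyWindow) -> bool:
    """Encounter-based eligibility for sites without defined membership."""
    return any(window.contains(d) for d in encounter_dates)


def age_at(birth_date: dt.date, reference: dt.date) -> int:
    """Completed years of age on the reference date (birthday-based)."""
    if birth_date > reference:
        raise ValueError(f"birth date {birth_date} is after reference {reference}")
    return (
        reference.year
        - birth_date.year
        - ((reference.month, reference.day) < (birth_date.month, birth_date.day))
    )


def latest_vital(
    records: Sequence[VitalRecord], kind: str, window: StudyWindow | None = None
) -> VitalRecord | None:
    """Most recent vital of ``kind`` (window-restricted when given); same-day
    ties are broken by the greatest ingestion ordinal."""
    candidates = [
        r
        for r in records
        if r.kind == kind and (window is None or window.contains(r.measure_date))
    ]
    if not candidates:
        return None
    return max(candidates, key=lambda r: (r.measure_date, r.record_seq))


def compute_bmi(weight_kg: float, height_m: float) -> float:
    if weight_kg <= 0 or height_m <= 0:
        raise ValueError("weight and height must be positive")
    return weight_kg / (height_m * height_m)


def plausible(kind: str, value: float, bounds: PlausibilityBounds) -> bool:
    """Half-open plausibility: the stated lower limits are excluded only when
    *below* them, the upper limits already at "equal or greater"."""
    if kind == "height":
        return bounds.height_min_m <= value < bounds.height_max_m
    if kind == "weight":
        return bounds.weight_min_kg <= value < bounds.weight_max_kg
    if kind == "bmi":
        return bounds.bmi_min <= value < bounds.bmi_max
    raise ValueError(f"unknown vital kind {kind!r}")


def classify_bmi(bmi: float, bounds: PlausibilityBounds | None = None) -> str:
    """BMI category on the half-open partition [23,25,30,35,40,50,90);
    plausible values below 23.0 are ``below_threshold``."""
    bounds = bounds or PlausibilityBounds()
    if not plausible("bmi", bmi, bounds):
        raise ValueError(f"BMI {bmi} outside plausible range; filter before classifying")
    idx = int(np.searchsorted(BMI_CATEGORY_BOUNDS, bmi, side="right"))
    if idx == 0:
        return "below_threshold"
    return BMI_CATEGORIES[idx - 1]


def resolve_person_bmi(
    vitals: Sequence[VitalRecord], window: StudyWindow
) -> tuple[float, str] | None:
    """One person's BMI: the latest in-window recorded BMI when present, else
    computed from the latest in-window weight and the latest height on
    record.  Input must already be plausibility-filtered."""
    recorded = latest_vital(vitals, "bmi", window)
    if recorded is not None:
        return recorded.value, "recorded"
    weight = latest_vital(vitals, "weight", window)
    height = latest_vital(vitals, "height", None)
    if weight is None or height is None:
        return None
    return compute_bmi(weight.value, height.value), "computed"


# ---------------------------------------------------------------------------
# vectorised pipeline


def _latest_by_person(df: pd.DataFrame) -> pd.Series:
    """person_id -> value of the (measure_date, record_seq)-latest row."""
    if df.empty:
        return pd.Series(dtype=float)
    picked = df.sort_values(["person_id", "measure_date", "record_seq"]).groupby("person_id").tail(1)
    return picked.set_index("person_id")["value"]


def _max_inwindow_coverage(enrollment: pd.DataFrame, window: StudyWindow, tol: int) -> pd.Series:
    """person_id -> longest merged-span day count inside the window."""
    if enrollment.empty:
        return pd.Series(dtype="int64")
    df = enrollment.sort_values(["person_id", "start_date"]).reset_index(drop=True)
    new_person = df["person_id"] != df["person_id"].shift()
    prev_end = df["end_date"].shift()
    gap_days = (df["start_date"] - prev_end).dt.days - 1
    new_group = new_person | (gap_days > tol)
    group = new_group.cumsum()
    merged = df.groupby(group).agg(
        person_id=("person_id", "first"),
        start=("start_date", "min"),
        end=("end_date", "max"),
    )
    lo = merged["start"].clip(lower=pd.Timestamp(window.start))
    hi = merged["end"].clip(upper=pd.Timestamp(window.end))
    cov = (hi - lo).dt.days + 1
    merged["cov"] = cov.clip(lower=0)
    return merged.groupby("person_id")["cov"].max()


def _pregnant_person_ids(tables: TableSet, window: StudyWindow, cfg: Config) -> set[str]:
    if tables.pregnancy is not None:
        flagged = tables.pregnancy
        return set(flagged.loc[flagged["pregnant_in_window"], "person_id"])
    dx = tables.diagnoses
    if dx.empty:
        return set()
    in_win = dx["dx_date"].between(pd.Timestamp(window.start), pd.Timestamp(window.end))
    preg = match_mask(dx["code"], cfg.pregnancy_prefixes)
    return set(dx.loc[in_win & preg, "person_id"])


def build_cohort(tables: TableSet, cfg: Config) -> tuple[pd.DataFrame, CohortFlow]:
    """Apply the eligibility and anthropometric pipeline; return the cohort
    member table and the attrition flow.

    The member table has one row per final cohort member: ``person_id``,
    ``bmi_value``, ``bmi_source`` (recorded/computed), ``bmi_category``,
    ``age_years``, ``site_id`` and ``nested_2009`` (≥ 1 enrollment day in
    2009, usable for retrospective linkage).
    """
    persons = tables.persons
    if persons.empty:
        raise ValueError("empty person table")
    window, bounds = cfg.window, cfg.bounds
    ws, we = pd.Timestamp(window.start), pd.Timestamp(window.end)

    # step 0: membership / encounter eligibility defines who enters the flow
    safety = persons["site_id"].isin(cfg.safety_net_sites)
    coverage = _max_inwindow_coverage(tables.enrollment, window, cfg.gap_tolerance_days)
    cov = persons["person_id"].map(coverage).fillna(0)
    member_ok = ~safety & (cov >= window.min_continuous_days)
    enc = tables.encounters
    if enc.empty:
        pc_persons: set[str] = set()
    else:
        pc = (enc["encounter_type"] == "primary_care") & enc["encounter_date"].between(ws, we)
        pc_persons = set(enc.loc[pc, "person_id"])
    encounter_ok = safety & persons["person_id"].isin(pc_persons)
    entering = persons.loc[member_ok | encounter_ok].copy()
    n_entering = len(entering)

    # step 1: age
    ref = window.age_reference_date
    bd = entering["birth_date"]
    age = ref.year - bd.dt.year - (
        (bd.dt.month * 100 + bd.dt.day) > (ref.month * 100 + ref.day)
    ).astype(int)
    entering["age_years"] = age
    adults = entering.loc[age >= 18]
    n_under18 = n_entering - len(adults)

    adult_ids = adults["person_id"]
    v = tables.vitals
    v = v.loc[v["person_id"].isin(set(adult_ids))]
    in_win = v["measure_date"].between(ws, we)
    heights_all = v.loc[v["kind"] == "height"]
    weights_win = v.loc[(v["kind"] == "weight") & in_win]
    bmis_win = v.loc[(v["kind"] == "bmi") & in_win]

    # step 2: missing anthropometrics, judged on raw (pre-plausibility) records
    raw_resolvable = adult_ids.isin(set(bmis_win["person_id"])) | (
        adult_ids.isin(set(weights_win["person_id"])) & adult_ids.isin(set(heights_all["person_id"]))
    )
    measured = adults.loc[raw_resolvable.values]
    n_missing = len(adults) - len(measured)

    # step 3: pregnancy
    pregnant_ids = _pregnant_person_ids(tables, window, cfg)
    not_pregnant = measured.loc[~measured["person_id"].isin(pregnant_ids)]
    n_pregnant = len(measured) - len(not_pregnant)

    # step 4: plausibility-filtered BMI resolution
    hb = heights_all.loc[
        (heights_all["value"] >= bounds.height_min_m) & (heights_all["value"] < bounds.height_max_m)
    ]
    wb = weights_win.loc[
        (weights_win["value"] >= bounds.weight_min_kg) & (weights_win["value"] < bounds.weight_max_kg)
    ]
    bb = bmis_win.loc[(bmis_win["value"] >= bounds.bmi_min) & (bmis_win["value"] < bounds.bmi_max)]
    latest_bmi = _latest_by_person(bb)
    latest_w = _latest_by_person(wb)
    latest_h = _latest_by_person(hb)

    frame = not_pregnant.set_index("person_id", drop=False)
    rec = frame.index.to_series().map(latest_bmi)
    w_ = frame.index.to_series().map(latest_w)
    h_ = frame.index.to_series().map(latest_h)
    computed = w_ / (h_ * h_)
    bmi_value = rec.where(rec.notna(), computed)
    bmi_source = np.where(rec.notna(), "recorded", "computed")
    resolvable = bmi_value.notna() & (bmi_value >= bounds.bmi_min) & (bmi_value < bounds.bmi_max)
    plaus = frame.loc[resolvable.values].copy()
    plaus["bmi_value"] = bmi_value[resolvable]
    plaus["bmi_source"] = bmi_source[resolvable.values]
    n_implausible = len(not_pregnant) - len(plaus)

    # step 5: cohort BMI threshold
    final = plaus.loc[plaus["bmi_value"] >= BMI_CATEGORY_BOUNDS[0]].copy()
    n_below = len(plaus) - len(final)

    idx = np.searchsorted(BMI_CATEGORY_BOUNDS, final["bmi_value"].to_numpy(), side="right")
    final["bmi_category"] = np.asarray(BMI_CATEGORIES, dtype=object)[idx - 1]

    cov09 = _max_inwindow_coverage(
        tables.enrollment,
        StudyWindow(dt.date(2009, 1, 1), dt.date(2009, 12, 31), dt.date(2009, 12, 31), 1),
        cfg.gap_tolerance_days,
    )
    final["nested_2009"] = final["person_id"].map(cov09).fillna(0).ge(1)

    members = final[
        ["person_id", "bmi_value", "bmi_source", "bmi_category", "age_years", "site_id", "nested_2009"]
    ].reset_index(drop=True)
    flow = CohortFlow(
        entering_members=n_entering,
        excluded_under18=n_under18,
        excluded_no_height_weight=n_missing,
        excluded_pregnant=n_pregnant,
        excluded_implausible=n_implausible,
        excluded_bmi_below_threshold=n_below,
        final_cohort=len(members),
    )
    return members, flow
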