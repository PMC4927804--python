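"""Computable phenotypes: glycemic status, hypertension, bariatric surgery, Charlson.

Diabetes follows the multi-site surveillance convention: one inpatient
diabetes diagnosis, or any combination of two other qualifying events
(outpatient diagnosis, anti-hyperglycemic dispense, HbA1c ≥ 6.5 %, fasting
glucose ≥ 126 mg/dL, random glucose ≥ 200 mg/dL) — by default on distinct
calendar dates.  Pre-diabetes needs a single in-band lab (HbA1c 5.7–6.4 %,
FPG 100–125, 2-h OGTT 140–199, endpoints inclusive) or a listed outpatient
790.2x code, and is superseded whenever the diabetes definition is met.
Hypertension needs one inpatient or two distinct-date outpatient 401–405
codes.  Bariatric surgery is an exact procedure-code match over a 2009–2013
lookback.  The Charlson score sums condition weights with hierarchy
supersession (a complicated form silences its uncomplicated form).
"""

from __future__ import annotations

import datetime as dt
import warnings
from typing import Sequence

import pandas as pd

from .config import CharlsonMap, Config, GlycemicThresholds, StudyWindow
from .schemas import (
    DispenseRecord,
    EncounterDiagnosis,
    LabRecord,
    ProcedureRecord,
    TableSet,
    code_matches,
)

__all__ = [
    "diabetes_status",
    "prediabetes_status",
    "hypertension_status",
    "bariatric_status",
    "charlson_score",
    "phenotype_all",
]

ANTI_HYPERGLYCEMIC = "anti_hyperglycemic"


def _dm_lab_qualifies(lab: LabRecord, thr: GlycemicThresholds) -> bool:
    if lab.test == "hba1c":
        return lab.value >= thr.hba1c_dm
    if lab.test == "fasting_glucose":
        return lab.value >= thr.fpg_dm
    if lab.test == "random_glucose":
        return lab.value >= thr.rpg_dm
    return False


def _pre_lab_qualifies(lab: LabRecord, thr: GlycemicThresholds) -> bool:
    if lab.test == "hba1c":
        return thr.hba1c_pre[0] <= lab.value <= thr.hba1c_pre[1]
    if lab.test == "fasting_glucose":
        return thr.fpg_pre[0] <= lab.value <= thr.fpg_pre[1]
    if lab.test == "ogtt_2h":
        return thr.ogtt_pre[0] <= lab.value <= thr.ogtt_pre[1]
    return False


def diabetes_status(
    diagnoses: Sequence[EncounterDiagnosis],
    dispenses: Sequence[DispenseRecord],
    labs: Sequence[LabRecord],
    window: StudyWindow,
    thresholds: GlycemicThresholds | None = None,
    *,
    distinct_dates: bool = True,
) -> bool:
    """One in-window inpatient diabetes diagnosis, or two other qualifying
    events (on distinct calendar dates unless ``distinct_dates=False``)."""
    thr = thresholds or GlycemicThresholds()
    other_dates: list[dt.date] = []
    for d in diagnoses:
        if not window.contains(d.dx_date):
            continue
        if code_matches(d.code, thr.dm_dx_prefixes):
            if d.setting == "inpatient":
                return True
            other_dates.append(d.dx_date)
    other_dates.extend(
        r.dispense_date
        for r in dispenses
        if window.contains(r.dispense_date) and r.drug_class == ANTI_HYPERGLYCEMIC
    )
    other_dates.extend(
        lab.result_date
        for lab in labs
        if window.contains(lab.result_date) and _dm_lab_qualifies(lab, thr)
    )
    n = len(set(other_dates)) if distinct_dates else len(other_dates)
    return n >= 2


def prediabetes_status(
    diagnoses: Sequence[EncounterDiagnosis],
    labs: Sequence[LabRecord],
    window: StudyWindow,
    thresholds: GlycemicThresholds | None = None,
    *,
    has_diabetes: bool,
) -> bool:
    """A single in-band lab or listed outpatient code qualifies — unless the
    person already meets the diabetes definition (supersession)."""
    if has_diabetes:
        return False
    thr = thresholds or GlycemicThresholds()
    for lab in labs:
        if window.contains(lab.result_date) and _pre_lab_qualifies(lab, thr):
            return True
    return any(
        window.contains(d.dx_date)
        and d.setting == "outpatient"
        and code_matches(d.code, thr.pre_dx_codes)
        for d in diagnoses
    )


def hypertension_status(
    diagnoses: Sequence[EncounterDiagnosis],
    window: StudyWindow,
    prefixes: Sequence[str] = ("401", "402", "403", "404", "405"),
    *,
    distinct_dates: bool = True,
) -> bool:
    """≥ 1 inpatient or ≥ 2 outpatient matching diagnoses in the window."""
    out_dates: list[dt.date] = []
    for d in diagnoses:
        if not window.contains(d.dx_date) or not code_matches(d.code, prefixes):
            continue
        if d.setting == "inpatient":
            return True
        out_dates.append(d.dx_date)
    n = len(set(out_dates)) if distinct_dates else len(out_dates)
    return n >= 2


def bariatric_status(
    procedures: Sequence[ProcedureRecord],
    codes: frozenset[str] | set[str],
    lookback: tuple[dt.date, dt.date] = (dt.date(2009, 1, 1), dt.date(2013, 12, 31)),
) -> bool:
    """Any procedure whose code exactly matches the configured list within
    the lookback window (exact match — procedure codes are not hierarchical
    the way diagnosis prefixes are)."""
    lo, hi = lookback
    return any(lo <= p.px_date <= hi and p.code in codes for p in procedures)


def _charlson_present(
    diagnoses: Sequence[EncounterDiagnosis], cmap: CharlsonMap
) -> set[str]:
    window = cmap.window
    present: set[str] = set()
    in_window = [d for d in diagnoses if window.contains(d.dx_date)]
    for cond in cmap.conditions:
        if any(code_matches(d.code, cond.prefixes) for d in in_window):
            present.add(cond.name)
    return present


def validate_charlson_overlap(cmap: CharlsonMap) -> None:
    """Warn when two non-hierarchy conditions share a code prefix boundary."""
    hier = {frozenset(pair) for pair in cmap.hierarchies}
    conds = cmap.conditions
    for i, a in enumerate(conds):
        for b in conds[i + 1 :]:
            if frozenset((a.name, b.name)) in hier:
                continue
            shared = [p for p in a.prefixes if code_matches(p, b.prefixes)] + [
                p for p in b.prefixes if code_matches(p, a.prefixes)
            ]
            if shared:
                warnings.warn(
                    f"Charlson conditions {a.name!r} and {b.name!r} have "
                    f"overlapping code prefixes (e.g. {shared[0]!r})",
                    stacklevel=2,
                )


def charlson_score(diagnoses: Sequence[EncounterDiagnosis], cmap: CharlsonMap) -> int:
    """Weighted comorbidity sum over in-window diagnoses with hierarchy
    supersession applied (one weight per hierarchy)."""
    present = _charlson_present(diagnoses, cmap)
    for superior, inferior in cmap.hierarchies:
        if superior in present:
            present.discard(inferior)
    return sum(c.weight for c in cmap.conditions if c.name in present)


# ---------------------------------------------------------------------------
# cohort-level driver


def _by_person(df: pd.DataFrame, ids: set[str], record, date_col: str, cols: Sequence[str]):
    """Group clinical rows into per-person record lists (dates as datetime.date)."""
    out: dict[str, list] = {}
    if df.empty:
        return out
    sub = df.loc[df["person_id"].isin(ids)]
    for row in sub.itertuples(index=False):
        d = getattr(row, date_col)
        rec = record(
            row.person_id,
            d.date() if hasattr(d, "date") else d,
            *[getattr(row, c) for c in cols],
        )
        out.setdefault(row.person_id, []).append(rec)
    return out


def phenotype_all(cohort: pd.DataFrame, tables: TableSet, cfg: Config) -> pd.DataFrame:
    """Evaluate every phenotype for every cohort member.

    Returns one row per member: ``person_id``, ``glycemic_status`` in
    {none, prediabetes, diabetes} (precedence enforced), ``hypertension``,
    ``bariatric_surgery`` and ``charlson_score``.  Members with no clinical
    records get an all-negative row.
    """
    ids = set(cohort["person_id"])
    window, thr = cfg.window, cfg.glycemic
    dx = _by_person(tables.diagnoses, ids, EncounterDiagnosis, "dx_date", ["code", "setting"])
    labs = _by_person(tables.labs, ids, LabRecord, "result_date", ["test", "value"])
    disp = _by_person(tables.dispenses, ids, DispenseRecord, "dispense_date", ["drug_class"])
    px = _by_person(tables.procedures, ids, ProcedureRecord, "px_date", ["code", "code_system"])

    rows = []
    empty: list = []
    for pid in cohort["person_id"]:
        d = dx.get(pid, empty)
        l = labs.get(pid, empty)
        dm = diabetes_status(
            d, disp.get(pid, empty), l, window, thr, distinct_dates=cfg.distinct_dates_required
        )
        pre = prediabetes_status(d, l, window, thr, has_diabetes=dm)
        glycemic = "diabetes" if dm else ("prediabetes" if pre else "none")
        rows.append(
            (
                pid,
                glycemic,
                hypertension_status(
                    d, window, cfg.hypertension_prefixes, distinct_dates=cfg.distinct_dates_required
                ),
                bariatric_status(px.get(pid, empty), cfg.bariatric_codes, cfg.bariatric_lookback),
                charlson_score(d, cfg.charlson),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["person_id", "glycemic_status", "hypertension", "bariatric_surgery", "charlson_score"],
    )
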