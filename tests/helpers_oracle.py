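"""Brute-force phenotype oracle, independent of the package's rules engine.

Re-derives every phenotype for one person by naive enumeration: diagnosis
prefix matching is re-implemented from the code-string grammar, the
two-event diabetes rule enumerates all event *pairs* with
itertools.combinations, and the Charlson score walks the condition list
directly.  Used to cross-check the engine on small synthetic populations.
"""

from __future__ import annotations

import datetime as dt
import itertools


def prefix_match(code: str, prefixes) -> bool:
    for p in prefixes:
        if code == p:
            return True
        # sub-code boundary: a dotted prefix extends by digits, an undotted
        # prefix only across a dot
        if "." in p and code.startswith(p):
            return True
        if "." not in p and code.startswith(p) and len(code) > len(p) and code[len(p)] == ".":
            return True
    return False


def in_window(d: dt.date, window) -> bool:
    return window.start <= d <= window.end


def oracle_diabetes(dx_rows, dispense_rows, lab_rows, window, thr, distinct_dates=True) -> bool:
    for d, code, setting in dx_rows:
        if in_window(d, window) and setting == "inpatient" and prefix_match(code, thr.dm_dx_prefixes):
            return True
    events = []
    for d, code, setting in dx_rows:
        if in_window(d, window) and setting == "outpatient" and prefix_match(code, thr.dm_dx_prefixes):
            events.append(("dx", d))
    for d, drug_class in dispense_rows:
        if in_window(d, window) and drug_class == "anti_hyperglycemic":
            events.append(("rx", d))
    for d, test, value in lab_rows:
        if not in_window(d, window):
            continue
        if (
            (test == "hba1c" and value >= thr.hba1c_dm)
            or (test == "fasting_glucose" and value >= thr.fpg_dm)
            or (test == "random_glucose" and value >= thr.rpg_dm)
        ):
            events.append(("lab", d))
    for a, b in itertools.combinations(events, 2):
        if not distinct_dates or a[1] != b[1]:
            return True
    return False


def oracle_prediabetes(dx_rows, lab_rows, window, thr, has_diabetes) -> bool:
    if has_diabetes:
        return False
    for d, test, value in lab_rows:
        if not in_window(d, window):
            continue
        if (
            (test == "hba1c" and thr.hba1c_pre[0] <= value <= thr.hba1c_pre[1])
            or (test == "fasting_glucose" and thr.fpg_pre[0] <= value <= thr.fpg_pre[1])
            or (test == "ogtt_2h" and thr.ogtt_pre[0] <= value <= thr.ogtt_pre[1])
        ):
            return True
    for d, code, setting in dx_rows:
        if in_window(d, window) and setting == "outpatient" and prefix_match(code, thr.pre_dx_codes):
            return True
    return False


def oracle_hypertension(dx_rows, window, prefixes, distinct_dates=True) -> bool:
    outpatient = []
    for d, code, setting in dx_rows:
        if not in_window(d, window) or not prefix_match(code, prefixes):
            continue
        if setting == "inpatient":
            return True
        outpatient.append(d)
    for a, b in itertools.combinations(outpatient, 2):
        if not distinct_dates or a != b:
            return True
    return False


def oracle_bariatric(px_rows, codes, lookback) -> bool:
    lo, hi = lookback
    return any(lo <= d <= hi and code in codes for d, code, _system in px_rows)


def oracle_charlson(dx_rows, cmap) -> int:
    present = set()
    for cond in cmap.conditions:
        for d, code, _setting in dx_rows:
            if in_window(d, cmap.window) and prefix_match(code, cond.prefixes):
                present.add(cond.name)
                break
    for sup, inf in cmap.hierarchies:
        if sup in present and inf in present:
            present.remove(inf)
    return sum(c.weight for c in cmap.conditions if c.name in present)


def person_rows(tables, pid):
    """Raw per-person event tuples straight from the tables."""
    dx = [
        (r.dx_date.date(), r.code, r.setting)
        for r in tables.diagnoses[tables.diagnoses["person_id"] == pid].itertuples()
    ]
    rx = [
        (r.dispense_date.date(), r.drug_class)
        for r in tables.dispenses[tables.dispenses["person_id"] == pid].itertuples()
    ]
    labs = [
        (r.result_date.date(), r.test, r.value)
        for r in tables.labs[tables.labs["person_id"] == pid].itertuples()
    ]
    px = [
        (r.px_date.date(), r.code, r.code_system)
        for r in tables.procedures[tables.procedures["person_id"] == pid].itertuples()
    ]
    return dx, rx, labs, px


def oracle_all(tables, pid, cfg) -> dict:
    dx, rx, labs, px = person_rows(tables, pid)
    dm = oracle_diabetes(dx, rx, labs, cfg.window, cfg.glycemic, cfg.distinct_dates_required)
    pre = oracle_prediabetes(dx, labs, cfg.window, cfg.glycemic, dm)
    return {
        "glycemic_status": "diabetes" if dm else ("prediabetes" if pre else "none"),
        "hypertension": oracle_hypertension(
            dx, cfg.window, cfg.hypertension_prefixes, cfg.distinct_dates_required
        ),
        "bariatric_surgery": oracle_bariatric(px, cfg.bariatric_codes, cfg.bariatric_lookback),
        "charlson_score": oracle_charlson(dx, cfg.charlson),
    }
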