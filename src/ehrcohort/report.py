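"""Attrition-flow report, prevalence tables, survey sampling and response rates.

Every percentage anywhere in the reporting layer goes through
:func:`percent` — 100·n/d rounded half-away-from-zero to two decimals —
so a printed percent can always be recomputed from the counts beside it.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import EXCLUSION_STEPS, CohortFlow
from .config import STRATUM_OF_CATEGORY, SurveyDesign

__all__ = [
    "percent",
    "flow_report",
    "PrevalenceTable",
    "prevalence_report",
    "sample_survey",
    "response_rate",
    "response_by_stratum",
]

STEP_LABELS = {
    "excluded_under18": "less than 18 years of age",
    "excluded_no_height_weight": "no height and weight recorded",
    "excluded_pregnant": "pregnant during the study window",
    "excluded_implausible": "implausible height, weight, or BMI",
    "excluded_bmi_below_threshold": "BMI below 23.0 kg/m2",
}


def percent(numerator: int, denominator: int) -> float:
    """100·numerator/denominator rounded half-away-from-zero to 2 decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    return float(
        (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


def flow_report(flow: CohortFlow) -> pd.DataFrame:
    """One row per exclusion step with its count and the running remainder.

    Refuses (raises) on a conservation violation rather than rebalancing."""
    if not flow.conserved:
        raise ValueError(
            "flow counts are not conserved: entering "
            f"{flow.entering_members} - exclusions {sum(flow.exclusions().values())} "
            f"!= final {flow.final_cohort}"
        )
    rows = [("eligible members entering", 0, flow.entering_members)]
    remaining = flow.entering_members
    for step in EXCLUSION_STEPS:
        excluded = getattr(flow, step)
        remaining -= excluded
        rows.append((STEP_LABELS[step], excluded, remaining))
    assert remaining == flow.final_cohort
    return pd.DataFrame(rows, columns=["step", "excluded", "remaining"])


@dataclass(frozen=True)
class PrevalenceTable:
    """Long-form prevalence rows plus per-attribute cross-site ranges."""

    rows: pd.DataFrame  # site_id, attribute, level, count, denominator, percent

    def site_range(self, attribute: str, level: str) -> tuple[float, float]:
        """(min, max) percent across sites for one attribute level."""
        sub = self.rows[
            (self.rows["attribute"] == attribute)
            & (self.rows["level"].astype(str) == str(level))
            & (self.rows["site_id"] != "ALL")
        ]
        if sub.empty:
            raise KeyError(f"no site rows for {attribute}={level}")
        return float(sub["percent"].min()), float(sub["percent"].max())

    def pooled(self, attribute: str, level: str) -> pd.Series:
        sub = self.rows[
            (self.rows["attribute"] == attribute)
            & (self.rows["level"].astype(str) == str(level))
            & (self.rows["site_id"] == "ALL")
        ]
        return sub.iloc[0]


def prevalence_report(
    cohort: pd.DataFrame,
    attributes: Sequence[str] = ("bmi_category",),
    persons: pd.DataFrame | None = None,
    phenotypes: pd.DataFrame | None = None,
) -> PrevalenceTable:
    """Site-level and pooled counts/percentages for each requested attribute.

    Demographic attributes (sex, race_ethnicity, insurance) require the
    ``persons`` table; phenotype attributes (glycemic_status, hypertension,
    bariatric_surgery) require the phenotype result table.  Denominator is
    the site's cohort size, so each attribute's counts sum to it.
    """
    df = cohort
    if persons is not None:
        df = df.merge(
            persons[["person_id", "sex", "race_ethnicity", "insurance"]], on="person_id", how="left"
        )
    if phenotypes is not None:
        df = df.merge(phenotypes, on="person_id", how="left")
    missing = [a for a in attributes if a not in df.columns]
    if missing:
        raise KeyError(f"attribute(s) {missing} not available; pass persons/phenotypes tables")

    rows = []
    site_groups = [("ALL", df)] + [(s, g) for s, g in df.groupby("site_id")]
    for site, g in site_groups:
        denom = len(g)
        for attr in attributes:
            for level, count in g[attr].value_counts().items():
                rows.append((site, attr, level, int(count), denom, percent(int(count), denom)))
    out = pd.DataFrame(
        rows, columns=["site_id", "attribute", "level", "count", "denominator", "percent"]
    ).sort_values(["attribute", "site_id", "level"], kind="stable", ignore_index=True)
    return PrevalenceTable(out)


def sample_survey(cohort: pd.DataFrame, design: SurveyDesign) -> pd.DataFrame:
    """Stratified simple random sample without replacement, per (site, stratum).

    Deterministic under ``design.seed`` and invariant to input row order
    (cells are sampled from person-id-sorted lists in a fixed cell order).
    Healthy-weight members are never sampled; obese classes 3 and 4 are
    pooled into one stratum.  An undersized cell raises, naming the cell
    and its shortfall.
    """
    df = cohort.copy()
    df["stratum"] = df["bmi_category"].map(STRATUM_OF_CATEGORY)
    sites = design.sites if design.sites is not None else tuple(sorted(df["site_id"].unique()))
    rng = np.random.default_rng(design.seed)
    picks = []
    for site in sites:
        for stratum in ("overweight", "obese1", "obese2", "obese3_plus"):
            alloc = design.allocations.get(stratum, 0)
            if alloc == 0:
                continue
            cell = df[(df["site_id"] == site) & (df["stratum"] == stratum)]
            cell = cell.sort_values("person_id", kind="stable")
            if len(cell) < alloc:
                raise ValueError(
                    f"cell (site={site!r}, stratum={stratum!r}) has {len(cell)} members, "
                    f"short {alloc - len(cell)} of the allocation {alloc}"
                )
            take = rng.choice(len(cell), size=alloc, replace=False)
            picks.append(cell.iloc[np.sort(take)])
    sampled = pd.concat(picks, ignore_index=True) if picks else df.iloc[0:0].copy()
    return sampled[["person_id", "site_id", "stratum", "bmi_category"]]


def response_rate(outcomes: pd.DataFrame) -> float:
    """Completed surveys as a percent of eligible sampled persons
    (selected minus ineligible)."""
    counts = outcomes["status"].value_counts()
    selected = int(counts.sum())
    ineligible = int(counts.get("ineligible", 0))
    completed = int(counts.get("completed", 0))
    eligible = selected - ineligible
    if eligible <= 0:
        raise ValueError("no eligible sampled persons")
    return percent(completed, eligible)


def response_by_stratum(outcomes: pd.DataFrame, attribute: str) -> pd.DataFrame:
    """Per-group sampled n, completed n (%), and not-returned n (%).

    The denominator is the group's sampled n, so completed + not-returned
    partitions each group; every status other than ``completed`` counts as
    not returned.
    """
    if attribute not in outcomes.columns:
        raise KeyError(f"outcomes table lacks grouping attribute {attribute!r}")
    rows = []
    for level, g in outcomes.groupby(attribute):
        n = len(g)
        completed = int((g["status"] == "completed").sum())
        not_returned = n - completed
        rows.append(
            (
                level,
                n,
                completed,
                percent(completed, n),
                not_returned,
                percent(not_returned, n),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[attribute, "n", "completed", "completed_pct", "not_returned", "not_returned_pct"],
    )
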