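"""Neighborhood socioeconomic estimation from census block-group profiles.

Health plans rarely hold individual education or income, so person-level
values are estimated as expectations under the person's block-group
distribution: the probability of each attainment level (or income band)
within the block group, times a configured numeric value per level (years
of schooling, band midpoint dollars).  Persons without a geocode link, or
whose block group has no profile, are reported with ``coverage =
no_geocode`` and no estimates.
"""

from __future__ import annotations

import logging
from typing import Mapping

import pandas as pd

PROBABILITY_SUM_TOL = 1e-9

logger = logging.getLogger(__name__)

__all__ = ["expected_level", "estimate_ses"]


def expected_level(probs: Mapping[str, float], values: Mapping[str, float]) -> float:
    """Expectation Σ_level p(level)·value(level) over one block-group domain."""
    total = sum(probs.values())
    if abs(total - 1.0) > PROBABILITY_SUM_TOL:
        raise ValueError(f"probabilities sum to {total!r}, not 1")
    acc = 0.0
    for level, p in probs.items():
        if p == 0:
            continue
        if level not in values:
            raise ValueError(f"probability mass on level {level!r} which has no configured value")
        acc += p * values[level]
    return acc


def estimate_ses(
    cohort: pd.DataFrame,
    geocodes: pd.DataFrame,
    block_groups: pd.DataFrame,
    education_values: Mapping[str, float],
    income_values: Mapping[str, float],
) -> pd.DataFrame:
    """Expected education and income per cohort member.

    Returns ``person_id``, ``expected_education``, ``expected_income``,
    ``coverage`` ({estimated, no_geocode}).  Block-group profiles arrive in
    long form (block_group_id, domain, level, probability).
    """
    values = {"education": education_values, "income": income_values}
    per_bg: dict[str, dict[str, float]] = {}
    for (bg, domain), grp in block_groups.groupby(["block_group_id", "domain"]):
        probs = dict(zip(grp["level"], grp["probability"]))
        per_bg.setdefault(bg, {})[domain] = expected_level(probs, values[domain])

    assign = geocodes.set_index("person_id")["block_group_id"]
    rows = []
    for pid in cohort["person_id"]:
        bg = assign.get(pid)
        profile = per_bg.get(bg) if bg is not None else None
        if profile is None or "education" not in profile or "income" not in profile:
            if bg is not None and profile is None:
                logger.warning("person %s assigned to unknown block group %s", pid, bg)
            rows.append((pid, float("nan"), float("nan"), "no_geocode"))
        else:
            rows.append((pid, profile["education"], profile["income"], "estimated"))
    return pd.DataFrame(
        rows, columns=["person_id", "expected_education", "expected_income", "coverage"]
    )
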