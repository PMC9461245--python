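"""Recoding of raw retrospective survey responses into analysis variables.

Turns the raw childhood-circumstance questions of a SHARE-style life-history
survey into the binary circumstance vector CI used by the estimator, and
builds the two outcome variants for a given age:

* adverse childhood experiences: ``harm`` is 1 when physical abuse from a
  parent OR from anybody else was reported "Often" or "Sometimes";
  ``relationship_bad`` is 1 when the relationship with the parents is rated
  "Fair" or "Poor".  The parental-understanding (child-neglect) question is
  deliberately not coded: it is highly correlated with the relationship
  rating and only the latter enters the circumstance set.
* background: ``financial_hardship`` is 1 for families reported as poor;
  ``child_bad_health`` is 1 for childhood self-assessed health fair or poor;
  ``parent_tertiary``, ``parent_absent``, ``gender_female`` pass through;
  ``household_size`` is kept as a small integer covariate, not binarised.
* outcomes at age a: ``outcome_any`` = at least one chronic condition
  reported by age a; ``outcome_ge_median`` = condition count at or above the
  median of the individual's own country×cohort cell at that age (lower
  median, so the >= rule is unambiguous on even cell sizes).

Records with any missing or unrecognised coded field are excluded by
listwise deletion; exclusions are counted per field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import CellDegenerate

__all__ = [
    "CIRCUMSTANCES",
    "DEFAULT_GROUPING",
    "SPLIT_HARM_GROUPING",
    "CodingReport",
    "code_ace",
    "code_background",
    "code_panel",
    "build_outcomes",
    "validate_grouping",
]

HARM_LEVELS = ("Often", "Sometimes", "Rarely", "Never")
UNDERSTOOD_LEVELS = ("A lot", "Some", "A little", "Not at all")
RELATIONSHIP_LEVELS = ("Excellent", "Very good", "Good", "Fair", "Poor")
SAH_LEVELS = ("excellent", "very good", "good", "fair", "poor")
FINANCE_LEVELS = ("well off", "average", "poor")

#: circumstance vector CI, in canonical column order
CIRCUMSTANCES = (
    "harm",
    "relationship_bad",
    "gender_female",
    "parent_absent",
    "financial_hardship",
    "parent_tertiary",
    "household_size",
    "child_bad_health",
)

#: four-group scheme: adverse childhood experiences, socio-economic
#: background, gender, childhood health
DEFAULT_GROUPING = {
    "ACE": ["harm", "relationship_bad"],
    "SES": ["parent_absent", "financial_hardship", "parent_tertiary",
            "household_size"],
    "GENDER": ["gender_female"],
    "CHILD_HEALTH": ["child_bad_health"],
}

#: variant with the ACE block split into its two components
SPLIT_HARM_GROUPING = {
    "HARM": ["harm"],
    "RELATIONSHIP": ["relationship_bad"],
    "SES": ["parent_absent", "financial_hardship", "parent_tertiary",
            "household_size"],
    "GENDER": ["gender_female"],
    "CHILD_HEALTH": ["child_bad_health"],
}


def validate_grouping(grouping: dict, circumstances=CIRCUMSTANCES) -> None:
    """Check that players partition the circumstance set exactly."""
    claimed = [c for cols in grouping.values() for c in cols]
    if len(claimed) != len(set(claimed)):
        raise ValueError("grouping assigns a circumstance to two players")
    if set(claimed) != set(circumstances):
        raise ValueError(
            f"grouping must partition {sorted(circumstances)}, "
            f"got {sorted(claimed)}"
        )


def code_ace(harm_parent, harm_other, relationship_rating):
    """Code the adverse-childhood-experience pair for one record.

    Returns ``(harm, relationship_bad)`` as 0/1 ints.  ``harm`` combines
    abuse from parents and from third parties into one indicator.
    """
    for v, levels, name in (
        (harm_parent, HARM_LEVELS, "harm_parent"),
        (harm_other, HARM_LEVELS, "harm_other"),
        (relationship_rating, RELATIONSHIP_LEVELS, "relationship_rating"),
    ):
        if v not in levels:
            raise ValueError(f"unknown level {v!r} for {name}")
    harm = int(harm_parent in ("Often", "Sometimes")
               or harm_other in ("Often", "Sometimes"))
    relationship_bad = int(relationship_rating in ("Fair", "Poor"))
    return harm, relationship_bad


def code_background(raw) -> dict:
    """Code the background circumstances for one record (mapping-like input)."""
    fin = raw["family_finance"]
    sah = raw["child_sah"]
    if fin not in FINANCE_LEVELS:
        raise ValueError(f"unknown level {fin!r} for family_finance")
    if sah not in SAH_LEVELS:
        raise ValueError(f"unknown level {sah!r} for child_sah")
    return {
        "financial_hardship": int(fin == "poor"),
        "parent_tertiary": int(bool(raw["parent_tertiary"])),
        "child_bad_health": int(sah in ("fair", "poor")),
        "parent_absent": int(bool(raw["parent_absent"])),
        "household_size": int(raw["household_size"]),
        "gender_female": int(raw["gender"] == "female"),
    }


@dataclass
class CodingReport:
    """Bookkeeping for a panel-coding pass: input = coded + excluded."""

    n_input: int = 0
    n_coded: int = 0
    n_excluded: int = 0
    excluded_by_field: dict = field(default_factory=dict)


def code_panel(panel: pd.DataFrame) -> tuple[pd.DataFrame, CodingReport]:
    """Vectorised coding of a raw panel into circumstance columns.

    Returns the coded frame (id/country/birth_year/disease columns carried
    through, plus one column per entry of :data:`CIRCUMSTANCES`) and a
    :class:`CodingReport`.  Rows with a missing or unrecognised value in any
    coded field are dropped; the report counts exclusions per field.
    """
    report = CodingReport(n_input=len(panel))

    checks = {
        "harm_parent": panel["harm_parent"].isin(HARM_LEVELS),
        "harm_other": panel["harm_other"].isin(HARM_LEVELS),
        "relationship_rating": panel["relationship_rating"].isin(RELATIONSHIP_LEVELS),
        "child_sah": panel["child_sah"].isin(SAH_LEVELS),
        "family_finance": panel["family_finance"].isin(FINANCE_LEVELS),
        "gender": panel["gender"].isin(("male", "female")),
        "parent_tertiary": panel["parent_tertiary"].notna(),
        "parent_absent": panel["parent_absent"].notna(),
        "household_size": panel["household_size"].notna(),
    }
    valid = pd.Series(True, index=panel.index)
    for fname, ok in checks.items():
        bad = int((~ok).sum())
        if bad:
            report.excluded_by_field[fname] = bad
        valid &= ok

    kept = panel.loc[valid].copy()
    report.n_coded = len(kept)
    report.n_excluded = report.n_input - report.n_coded

    coded = kept.drop(
        columns=["harm_parent", "harm_other", "parent_understood",
                 "relationship_rating", "child_sah", "family_finance"],
        errors="ignore",
    )
    coded["harm"] = (
        kept["harm_parent"].isin(("Often", "Sometimes"))
        | kept["harm_other"].isin(("Often", "Sometimes"))
    ).astype(int)
    coded["relationship_bad"] = (
        kept["relationship_rating"].isin(("Fair", "Poor")).astype(int)
    )
    coded["gender_female"] = (kept["gender"] == "female").astype(int)
    coded["parent_absent"] = kept["parent_absent"].astype(bool).astype(int)
    coded["financial_hardship"] = (kept["family_finance"] == "poor").astype(int)
    coded["parent_tertiary"] = kept["parent_tertiary"].astype(bool).astype(int)
    coded["household_size"] = kept["household_size"].astype(int)
    coded["child_bad_health"] = (
        kept["child_sah"].isin(("fair", "poor")).astype(int)
    )
    return coded, report


def build_outcomes(records: pd.DataFrame, age: int, cell=None) -> pd.DataFrame:
    """Both outcome variants at ``age`` for the records of one cell.

    ``outcome_any`` is 1 for a positive condition count by that age;
    ``outcome_ge_median`` compares the count with the cell's lower median at
    that age (count >= median).  The median is computed on the analysis
    sample passed in, i.e. after coding exclusions.
    """
    if len(records) == 0:
        raise CellDegenerate("empty cell", cell=cell)
    col = f"dis_count_{age}"
    if col not in records.columns:
        raise KeyError(f"no disease count column {col!r}")
    counts = records[col].astype(int).to_numpy()
    median = np.quantile(counts, 0.5, method="inverted_cdf")
    return pd.DataFrame(
        {
            "outcome_any": (counts >= 1).astype(int),
            "outcome_ge_median": (counts >= median).astype(int),
        },
        index=records.index,
    )
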