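"""Study orchestration over the country × cohort × age grid.

Runs the full design: for every cell of the grid, code the outcome at that
age, estimate the cell's dissimilarity index, and (optionally) decompose it
by circumstance group.  Supports gender stratification (gender is removed
from the circumstance set within strata), the four canonical birth-cohort
partitions plus custom bounds, and an age-availability rule that suppresses
ages a cohort cannot have reached by the interview year.

Every grid cell appears exactly once in the result table; cells that cannot
be estimated are recorded as missing with a reason code rather than aborting
the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coding
from .coding import CIRCUMSTANCES, DEFAULT_GROUPING, build_outcomes, code_panel
from .exceptions import CellDegenerate, RankDeficientDesign, ShareUndefined
from .iop import CellChecks, estimate_cell
from .shapley import ShapleySpec, shapley_decompose

logger = logging.getLogger(__name__)

__all__ = [
    "COHORT_PARTITIONS",
    "StudyConfig",
    "assign_cohort",
    "cohort_label",
    "max_age_for_cohort",
    "run_study",
    "summarize",
]

#: canonical birth-cohort partitions (bounds inclusive on both ends)
COHORT_PARTITIONS = {
    "6yr_baseline": ((1940, 1945), (1946, 1951), (1952, 1957), (1958, 1963)),
    "5yr": ((1941, 1945), (1946, 1950), (1951, 1955), (1956, 1960)),
    "6yr_alt": ((1939, 1944), (1945, 1950), (1951, 1956), (1957, 1962)),
    "10yr": ((1935, 1944), (1945, 1954), (1955, 1964)),
}

DEFAULT_AGE_GRID = (25, 30, 35, 40, 45, 50, 55, 60, 65)


@dataclass
class StudyConfig:
    """Design of one full run.

    cohort_partition : a key of :data:`COHORT_PARTITIONS` or a sequence of
        (first, last) birth-year pairs, inclusive on both ends.
    outcome_variant : "any_chronic" (at least one condition) or "ge_median"
        (condition count at or above the cell median).
    grouping : Shapley players, a partition of the circumstance set.
    stratify_gender : run every cell separately for men and women, with
        gender removed from the circumstance set and the grouping.
    age_cap : "interview" applies the availability rule (interview_year −
        cohort last birth year, floored to the grid); a mapping cohort
        index -> max age sets explicit caps; None disables suppression.
    decompose : compute per-player Shapley shares per cell (exact method).
    """

    cohort_partition: object = "6yr_baseline"
    age_grid: tuple = DEFAULT_AGE_GRID
    outcome_variant: str = "any_chronic"
    grouping: dict = field(default_factory=lambda: dict(DEFAULT_GROUPING))
    stratify_gender: bool = False
    interview_year: int = 2017
    age_cap: object = "interview"
    decompose: bool = True
    checks: CellChecks = field(default_factory=CellChecks)

    @property
    def cohort_bounds(self) -> tuple:
        if isinstance(self.cohort_partition, str):
            try:
                return COHORT_PARTITIONS[self.cohort_partition]
            except KeyError:
                raise ValueError(
                    f"unknown cohort partition {self.cohort_partition!r}; "
                    f"known: {sorted(COHORT_PARTITIONS)}"
                ) from None
        return tuple(tuple(b) for b in self.cohort_partition)

    @property
    def outcome_column(self) -> str:
        try:
            return {"any_chronic": "outcome_any",
                    "ge_median": "outcome_ge_median"}[self.outcome_variant]
        except KeyError:
            raise ValueError(
                f"unknown outcome variant {self.outcome_variant!r}") from None

    def validate(self) -> None:
        bounds = self.cohort_bounds
        for lo, hi in bounds:
            if lo > hi:
                raise ValueError(f"cohort bounds ({lo},{hi}) reversed")
        for (_, hi), (lo2, _) in zip(bounds, bounds[1:]):
            if lo2 <= hi:
                raise ValueError("cohort bounds overlap or are unordered")
        self.outcome_column
        coding.validate_grouping(self.grouping)


def assign_cohort(birth_year: int, partition) -> int | None:
    """Cohort index for a birth year, or None if outside every cohort.

    Bounds are inclusive on both ends: 1945 belongs to 1940–45 and 1946 to
    1946–51 under the baseline partition.
    """
    for i, (lo, hi) in enumerate(partition):
        if lo <= birth_year <= hi:
            return i
    return None


def cohort_label(bounds) -> str:
    lo, hi = bounds
    return f"{lo}-{hi % 100:02d}"


def max_age_for_cohort(bounds, age_grid, interview_year: int = 2017):
    """Oldest grid age the cohort's youngest member has reached.

    Returns None when no grid age is attainable.
    """
    attained = interview_year - bounds[1]
    eligible = [a for a in age_grid if a <= attained]
    return max(eligible) if eligible else None


def _cap_for(config: StudyConfig, cohort_idx: int):
    if config.age_cap is None:
        return None
    if config.age_cap == "interview":
        return max_age_for_cohort(
            config.cohort_bounds[cohort_idx], config.age_grid,
            config.interview_year)
    return config.age_cap.get(cohort_idx)


def _strata(config: StudyConfig):
    if config.stratify_gender:
        return [("male", 0), ("female", 1)]
    return [("all", None)]


def _stratum_design(config: StudyConfig, stratified: bool):
    """Circumstances and grouping for a stratum.

    Within gender strata the gender column is constant, so it is removed
    from the circumstance set and its player dropped from the grouping.
    """
    if not stratified:
        return list(CIRCUMSTANCES), dict(config.grouping)
    circ = [c for c in CIRCUMSTANCES if c != "gender_female"]
    grouping = {}
    for label, cols in config.grouping.items():
        kept = [c for c in cols if c != "gender_female"]
        if kept:
            grouping[label] = kept
    return circ, grouping


def run_study(panel: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Execute the full grid and return the result table.

    One row per (country, cohort, age, stratum) with status ∈
    {ok, degenerate, suppressed, missing} — "degenerate" marks attempted
    cells the estimator had to drop (e.g. no cases), "missing" cells with no
    records — the cell size, mean predicted probability,
    D index, reliability flag, and one ``rc_<player>`` column per Shapley
    player when decomposition is on.  Deterministic given the panel and the
    config: rows are emitted in canonical grid order.
    """
    config.validate()
    coded, report = code_panel(panel)
    if report.n_excluded:
        logger.info("coding excluded %d of %d records",
                    report.n_excluded, report.n_input)

    bounds = config.cohort_bounds
    coded = coded.copy()
    coded["cohort_idx"] = [
        assign_cohort(by, bounds) for by in coded["birth_year"].astype(int)
    ]
    coded = coded[coded["cohort_idx"].notna()]
    coded["cohort_idx"] = coded["cohort_idx"].astype(int)

    countries = sorted(panel["country"].astype(str).unique())
    strata = _strata(config)
    outcome_col = config.outcome_column

    rows = []
    n_attempted = n_suppressed = n_missing = 0
    for country in countries:
        for ci, cb in enumerate(bounds):
            cap = _cap_for(config, ci)
            cell_base = coded[(coded["country"] == country)
                              & (coded["cohort_idx"] == ci)]
            for age in config.age_grid:
                for stratum_label, female in strata:
                    stratified = female is not None
                    circ, grouping = _stratum_design(config, stratified)
                    row = {
                        "country": country,
                        "cohort": cohort_label(cb),
                        "age": age,
                        "outcome_variant": config.outcome_variant,
                        "stratum": stratum_label,
                        "status": "ok",
                        "reason": "",
                        "n": np.nan,
                        "ybar": np.nan,
                        "d_index": np.nan,
                        "reliable": False,
                    }
                    if config.decompose:
                        for p in grouping:
                            row[f"rc_{p}"] = np.nan

                    if cap is not None and age > cap:
                        row["status"] = "suppressed"
                        row["reason"] = "age_unobserved"
                        n_suppressed += 1
                        rows.append(row)
                        continue

                    df = cell_base
                    if stratified:
                        df = df[df["gender_female"] == female]
                    if len(df) == 0:
                        row["status"] = "missing"
                        row["reason"] = "no records"
                        n_missing += 1
                        rows.append(row)
                        continue

                    n_attempted += 1
                    cell_id = (country, cohort_label(cb), age, stratum_label)
                    try:
                        df = df.copy()
                        df[["outcome_any", "outcome_ge_median"]] = (
                            build_outcomes(df, age, cell=cell_id))
                        res = estimate_cell(df, outcome_col, circ,
                                            cell=cell_id, checks=config.checks)
                    except (CellDegenerate, RankDeficientDesign) as err:
                        # attempted but unestimable; reported missing-with-
                        # reason, like a dropped low-prevalence cell
                        row["status"] = "degenerate"
                        row["reason"] = str(err)
                        row["n"] = len(df)
                        rows.append(row)
                        continue

                    row.update(n=res.n, ybar=res.ybar, d_index=res.d_index,
                               reliable=res.reliable,
                               reason="; ".join(res.reasons))
                    if config.decompose:
                        try:
                            shap = shapley_decompose(
                                df, ShapleySpec(players=grouping),
                                outcome_col, cell=cell_id)
                            for p, share in shap.rc.items():
                                row[f"rc_{p}"] = share
                        except ShareUndefined:
                            row["reason"] = (row["reason"] + "; " if row["reason"]
                                             else "") + "shares undefined (D=0)"
                    rows.append(row)

    table = pd.DataFrame(rows)
    grid_size = len(countries) * len(bounds) * len(config.age_grid) * len(strata)
    assert len(table) == grid_size, "grid incomplete"
    assert n_attempted + n_suppressed + n_missing == grid_size
    table.attrs["n_attempted"] = n_attempted
    table.attrs["n_suppressed"] = n_suppressed
    table.attrs["n_missing"] = n_missing
    table.attrs["coding_report"] = report
    return table


# ---------------------------------------------------------------------------
# summaries mirroring the study's reporting formats
# ---------------------------------------------------------------------------

def summarize(results: pd.DataFrame, view: str) -> pd.DataFrame:
    """Summary tables over a result table.

    view = "d_by_age" : D by age (columns) per country × cohort (rows).
    view = "shares_by_age" : cross-country unweighted mean of per-player
        shares by cohort × age, in percent.
    view = "country_bars" : per-country player shares in percent at ages
        30/40/50/60.

    Unreliable or missing cells are excluded; the number excluded is in
    ``.attrs["n_excluded"]``.
    """
    if len(results) == 0:
        raise ValueError("empty result table")
    ok = results[(results["status"] == "ok") & results["reliable"]]
    excluded = len(results) - len(ok)

    if view == "d_by_age":
        out = ok.pivot_table(index=["country", "cohort", "stratum"],
                             columns="age", values="d_index")
    elif view in ("shares_by_age", "country_bars"):
        rc_cols = [c for c in results.columns if c.startswith("rc_")]
        if not rc_cols:
            raise ValueError("result table carries no Shapley shares")
        long = ok.melt(
            id_vars=["country", "cohort", "age", "stratum"],
            value_vars=rc_cols, var_name="player", value_name="share",
        ).dropna(subset=["share"])
        long["player"] = long["player"].str.removeprefix("rc_")
        long["share_pct"] = 100.0 * long["share"]
        if view == "shares_by_age":
            out = long.pivot_table(index=["cohort", "age", "stratum"],
                                   columns="player", values="share_pct",
                                   aggfunc="mean")
        else:
            bars = long[long["age"].isin((30, 40, 50, 60))]
            out = bars.pivot_table(
                index=["country", "cohort", "age", "stratum"],
                columns="player", values="share_pct")
    else:
        raise ValueError(f"unknown view {view!r}")
    out.attrs["n_excluded"] = excluded
    return out
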