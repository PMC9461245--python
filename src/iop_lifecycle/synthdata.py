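"""Synthetic survey panels with the structure the estimator assumes.

Generates individual-level records shaped like a retrospective European
ageing survey: raw childhood-circumstance responses (ordinal abuse and
relationship questions, childhood self-assessed health, family finances,
parental education, absent parent, household size) and a chronic-condition
count at each age of a 25–65 grid.

Statistical structure
---------------------
*Circumstances* come from a one-factor Gaussian copula: each individual has
a shared standard-normal latent factor; every circumstance thresholds
``loading * factor + sqrt(1 - loading^2) * noise`` at the normal quantile of
its target marginal prevalence.  Loadings control pairwise association
(childhood adversities are positively associated; protective factors can
take negative loadings); marginals are hit exactly in expectation.
Household size maps its latent through a Poisson quantile (2 + extra
members) instead of a single threshold.

*Diseases* follow an age-indexed logistic occurrence process: at each grid
age ``a`` a new condition occurs with probability

    logistic( intercept(a) + cohort_shift + sum_c effect_c(a) * x_c )

and the count accumulates occurrences, so it is monotone in age by
construction.  Effects are linear in age (a base value at the reference age
plus a per-decade slope), which reproduces a cumulative-advantage pattern
when slopes are positive; per-cohort multipliers on the effects emulate
cohort divergence.

Raw ordinal responses are expanded from the coded binaries with fixed
conditional category probabilities, so re-coding the panel recovers the
generated binaries exactly.

Reproducibility: one master seed; each country×cohort cell draws from its
own stream keyed by a stable hash of the cell label, so cells regenerate
identically in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm, poisson

__all__ = [
    "CircumstanceSpec",
    "AgeProfile",
    "HouseholdSpec",
    "GeneratorConfig",
    "default_config",
    "generate_panel",
    "write_panel",
]

#: binary coded circumstances the copula draws directly
BINARY_CIRCUMSTANCES = (
    "harm",
    "relationship_bad",
    "gender_female",
    "parent_absent",
    "financial_hardship",
    "parent_tertiary",
    "child_bad_health",
)


@dataclass(frozen=True)
class CircumstanceSpec:
    """Marginal prevalence in (0,1) and loading in [-1,1] on the shared factor."""

    prevalence: float
    loading: float = 0.0


@dataclass(frozen=True)
class AgeProfile:
    """Log-odds linear in age: ``base + slope_per_decade * (age - ref) / 10``."""

    base: float
    slope_per_decade: float = 0.0

    def at(self, age: float, ref: float) -> float:
        return self.base + self.slope_per_decade * (age - ref) / 10.0


@dataclass(frozen=True)
class HouseholdSpec:
    """Household size = 2 + Poisson(mean_extra), copula-coupled via loading."""

    mean_extra: float = 2.5
    loading: float = 0.0


@dataclass
class GeneratorConfig:
    """Full specification of one synthetic panel.

    The defaults are the package's reference study conditions: prevalences
    and effect sizes in the range typical of retrospective ageing surveys,
    mild positive association among childhood adversities, and a disease
    hazard rising with age.
    """

    n_per_cell: int = 1000
    countries: tuple = ("AT", "DE", "SE")
    cohort_bounds: tuple = ((1940, 1945), (1946, 1951), (1952, 1957), (1958, 1963))
    age_grid: tuple = (25, 30, 35, 40, 45, 50, 55, 60, 65)
    circumstance_spec: dict = field(default_factory=lambda: {
        "harm": CircumstanceSpec(0.20, 0.50),
        "relationship_bad": CircumstanceSpec(0.10, 0.50),
        "gender_female": CircumstanceSpec(0.50, 0.0),
        "parent_absent": CircumstanceSpec(0.12, 0.30),
        "financial_hardship": CircumstanceSpec(0.25, 0.40),
        "parent_tertiary": CircumstanceSpec(0.15, -0.30),
        "child_bad_health": CircumstanceSpec(0.08, 0.40),
    })
    household: HouseholdSpec = field(
        default_factory=lambda: HouseholdSpec(2.5, 0.30))
    effect_profile: dict = field(default_factory=lambda: {
        "harm": AgeProfile(0.35, 0.05),
        "relationship_bad": AgeProfile(0.25, 0.05),
        "gender_female": AgeProfile(0.10, 0.0),
        "parent_absent": AgeProfile(0.15, 0.0),
        "financial_hardship": AgeProfile(0.30, 0.05),
        "parent_tertiary": AgeProfile(-0.25, 0.0),
        "household_size": AgeProfile(0.03, 0.0),
        "child_bad_health": AgeProfile(0.40, 0.0),
    })
    intercept_profile: AgeProfile = field(
        default_factory=lambda: AgeProfile(-3.2, 0.50))
    cohort_shift: tuple | None = None          # per-cohort additive log-odds
    cohort_effect_scale: tuple | None = None   # per-cohort multiplier on effects
    age_ref: float = 25.0
    seed: int = 0

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        if not self.countries:
            raise ValueError("countries must be non-empty")
        bounds = list(self.cohort_bounds)
        for lo, hi in bounds:
            if lo > hi:
                raise ValueError(f"cohort_bounds pair ({lo},{hi}) reversed")
        for (_, hi), (lo2, _) in zip(bounds, bounds[1:]):
            if lo2 <= hi:
                raise ValueError("cohort_bounds overlap or are unordered")
        ages = list(self.age_grid)
        if any(b <= a for a, b in zip(ages, ages[1:])) or not ages:
            raise ValueError("age_grid must be non-empty, strictly increasing")
        for name, spec in self.circumstance_spec.items():
            if not 0.0 < spec.prevalence < 1.0:
                raise ValueError(
                    f"circumstance_spec[{name!r}].prevalence must be in (0,1)")
            if abs(spec.loading) > 1.0:
                raise ValueError(
                    f"circumstance_spec[{name!r}].loading must be in [-1,1]")
        if abs(self.household.loading) > 1.0:
            raise ValueError("household.loading must be in [-1,1]")
        if self.household.mean_extra < 0:
            raise ValueError("household.mean_extra must be >= 0")
        missing = set(self.circumstance_spec) - set(self.effect_profile)
        if missing:
            raise ValueError(f"effect_profile missing entries for {sorted(missing)}")
        for attr in ("cohort_shift", "cohort_effect_scale"):
            v = getattr(self, attr)
            if v is not None and len(v) != len(bounds):
                raise ValueError(f"{attr} must have one entry per cohort")

    def replace(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


def default_config(**overrides) -> GeneratorConfig:
    """Reference configuration; keyword overrides are applied on top."""
    return GeneratorConfig().replace(**overrides)


# ---------------------------------------------------------------------------
# raw ordinal expansion: conditional category probabilities given the coded
# binary; chosen so that re-coding the raw responses inverts the expansion
# ---------------------------------------------------------------------------

_ABUSIVE = (("Often", 0.3), ("Sometimes", 0.7))
_BENIGN = (("Rarely", 0.3), ("Never", 0.7))
_REL_BAD = (("Fair", 0.75), ("Poor", 0.25))
_REL_GOOD = (("Excellent", 0.35), ("Very good", 0.35), ("Good", 0.30))
_UNDERSTOOD_BAD = (("Some", 0.2), ("A little", 0.5), ("Not at all", 0.3))
_UNDERSTOOD_GOOD = (("A lot", 0.5), ("Some", 0.35), ("A little", 0.12),
                    ("Not at all", 0.03))
_SAH_BAD = (("fair", 0.7), ("poor", 0.3))
_SAH_GOOD = (("excellent", 0.35), ("very good", 0.35), ("good", 0.30))
_FIN_GOOD = (("well off", 0.3), ("average", 0.7))
# among harm=1: abusive parent only / other only / both
_HARM_SOURCE = (("parent", 0.60), ("other", 0.25), ("both", 0.15))


def _draw(rng, n, table):
    levels = [t[0] for t in table]
    probs = [t[1] for t in table]
    return rng.choice(levels, size=n, p=probs)


def _expand_conditional(rng, flag, table_if_1, table_if_0):
    out = np.empty(flag.shape, dtype=object)
    idx1 = flag == 1
    out[idx1] = _draw(rng, int(idx1.sum()), table_if_1)
    out[~idx1] = _draw(rng, int((~idx1).sum()), table_if_0)
    return out


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _cell_rng(seed: int, country: str, cohort_idx: int) -> np.random.Generator:
    # stable per-cell stream: hash the label, never Python's salted hash()
    key = zlib.crc32(f"{country}|{cohort_idx}".encode())
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def _generate_cell(config: GeneratorConfig, country: str,
                   cohort_idx: int) -> pd.DataFrame:
    rng = _cell_rng(config.seed, country, cohort_idx)
    n = config.n_per_cell
    lo, hi = config.cohort_bounds[cohort_idx]

    factor = rng.standard_normal(n)
    x = {}
    for name, spec in config.circumstance_spec.items():
        noise = rng.standard_normal(n)
        latent = spec.loading * factor + np.sqrt(1 - spec.loading**2) * noise
        x[name] = (latent <= norm.ppf(spec.prevalence)).astype(int)

    h = config.household
    latent = h.loading * factor + np.sqrt(1 - h.loading**2) * rng.standard_normal(n)
    u = np.clip(norm.cdf(latent), 1e-12, 1 - 1e-12)
    household_size = 2 + poisson.ppf(u, mu=h.mean_extra).astype(int)

    # disease occurrence process
    shift = 0.0 if config.cohort_shift is None else config.cohort_shift[cohort_idx]
    scale = (1.0 if config.cohort_effect_scale is None
             else config.cohort_effect_scale[cohort_idx])
    counts = np.zeros(n, dtype=int)
    count_cols = {}
    for age in config.age_grid:
        lin = np.full(n, config.intercept_profile.at(age, config.age_ref) + shift)
        for name, prof in config.effect_profile.items():
            coef = scale * prof.at(age, config.age_ref)
            if name == "household_size":
                lin += coef * (household_size - 2)
            else:
                lin += coef * x[name]
        p = 1.0 / (1.0 + np.exp(-lin))
        counts = counts + (rng.random(n) < p).astype(int)
        count_cols[f"dis_count_{age}"] = counts.copy()

    harm = x["harm"]
    source = np.full(n, "", dtype=object)
    source[harm == 1] = _draw(rng, int(harm.sum()), _HARM_SOURCE)
    harm_parent = np.array(_draw(rng, n, _BENIGN), dtype=object)
    harm_other = np.array(_draw(rng, n, _BENIGN), dtype=object)
    for src, cols in (("parent", ("harm_parent",)), ("other", ("harm_other",)),
                      ("both", ("harm_parent", "harm_other"))):
        idx = source == src
        k = int(idx.sum())
        if "harm_parent" in cols:
            harm_parent[idx] = _draw(rng, k, _ABUSIVE)
        if "harm_other" in cols:
            harm_other[idx] = _draw(rng, k, _ABUSIVE)

    df = pd.DataFrame({
        "id": [f"{country}-{cohort_idx}-{i:06d}" for i in range(n)],
        "country": country,
        "birth_year": rng.integers(lo, hi + 1, size=n),
        "gender": np.where(x["gender_female"] == 1, "female", "male"),
        "harm_parent": harm_parent,
        "harm_other": harm_other,
        "parent_understood": _expand_conditional(
            rng, x["relationship_bad"], _UNDERSTOOD_BAD, _UNDERSTOOD_GOOD),
        "relationship_rating": _expand_conditional(
            rng, x["relationship_bad"], _REL_BAD, _REL_GOOD),
        "child_sah": _expand_conditional(
            rng, x["child_bad_health"], _SAH_BAD, _SAH_GOOD),
        "family_finance": np.where(
            x["financial_hardship"] == 1, "poor",
            _draw(rng, n, _FIN_GOOD)),
        "parent_tertiary": x["parent_tertiary"].astype(bool),
        "parent_absent": x["parent_absent"].astype(bool),
        "household_size": household_size,
    })
    for col, vals in count_cols.items():
        df[col] = vals
    return df


def generate_panel(config: GeneratorConfig) -> pd.DataFrame:
    """Generate the full panel: n_per_cell records per country×cohort cell.

    Deterministic given ``config.seed``; each cell has its own stream so
    changing the country list leaves other cells' records unchanged.
    """
    config.validate()
    frames = [
        _generate_cell(config, country, ci)
        for country in config.countries
        for ci in range(len(config.cohort_bounds))
    ]
    return pd.concat(frames, ignore_index=True)


def write_panel(panel: pd.DataFrame, path) -> None:
    """Write the panel as flat CSV, one row per respondent."""
    panel.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# named scenarios
# ---------------------------------------------------------------------------

def null_effects() -> dict:
    """Zero effect for every circumstance: disease independent of circumstances."""
    return {name: AgeProfile(0.0, 0.0) for name in
            list(BINARY_CIRCUMSTANCES) + ["household_size"]}


def null_config(**overrides) -> GeneratorConfig:
    """Null scenario: circumstances exist but carry no disease effect.

    The population dissimilarity index is exactly 0 at every age; estimated
    values are small and positive (finite-sample bias of a non-negative
    index).
    """
    return default_config(effect_profile=null_effects(), **overrides)


def cumulative_advantage_effects(base: float = 0.05,
                                 slope: float = 0.45) -> dict:
    """Effect profiles for the cumulative-advantage scenario.

    The main childhood adversities (harm, bad parental relationship,
    financial hardship; childhood bad health at half strength) start at a
    small log-odds effect at age 25 and gain ``slope`` log-odds per decade,
    so circumstance-linked disadvantage accumulates with age.  Demographic
    and protective factors keep small, nearly flat effects.
    """
    return {
        "harm": AgeProfile(base, slope),
        "relationship_bad": AgeProfile(base, slope),
        "gender_female": AgeProfile(0.05, 0.10),
        "parent_absent": AgeProfile(0.05, 0.10),
        "financial_hardship": AgeProfile(base, slope),
        "parent_tertiary": AgeProfile(-0.05, -0.10),
        "household_size": AgeProfile(0.01, 0.0),
        "child_bad_health": AgeProfile(base, slope / 2),
    }


def cumulative_advantage_config(**overrides) -> GeneratorConfig:
    """Reference cumulative-advantage scenario.

    Flat baseline hazard (log-odds −3.9 per age step) with age-increasing
    circumstance effects; the population D-by-age curve rises monotonically
    from ~0.03 at age 25 to ~0.29 at 65 while any-condition prevalence
    reaches ~0.35.  Cell size defaults to 50 000 so that the small-sample
    upward bias of the index at low case counts (young ages) stays well
    below the true age-to-age increments.
    """
    base = dict(
        n_per_cell=50_000,
        countries=("A",),
        effect_profile=cumulative_advantage_effects(),
        intercept_profile=AgeProfile(-3.9, 0.0),
    )
    base.update(overrides)
    return default_config(**base)
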