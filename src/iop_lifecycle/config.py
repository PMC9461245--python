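"""YAML configuration loading for the command-line interface.

A config file has two top-level sections, both optional, whose keys mirror
the :class:`~iop_lifecycle.synthdata.GeneratorConfig` and
:class:`~iop_lifecycle.pipeline.StudyConfig` fields::

    generator:
      n_per_cell: 800
      countries: [AT, DE, SE]
      seed: 7
      circumstance_spec:
        harm: {prevalence: 0.2, loading: 0.5}
      effect_profile:
        harm: {base: 0.35, slope_per_decade: 0.05}
      intercept_profile: {base: -3.2, slope_per_decade: 0.5}
    study:
      cohort_partition: 6yr_baseline
      outcome_variant: any_chronic
      stratify_gender: false

Unspecified keys keep the package defaults.
"""

from __future__ import annotations

import yaml

from .iop import CellChecks
from .pipeline import StudyConfig
from .synthdata import AgeProfile, CircumstanceSpec, GeneratorConfig, HouseholdSpec

__all__ = ["load_config", "generator_from_dict", "study_from_dict"]


def _as_tuple_pairs(v):
    return tuple(tuple(int(x) for x in pair) for pair in v)


def generator_from_dict(d: dict) -> GeneratorConfig:
    cfg = GeneratorConfig()
    d = dict(d or {})
    if "circumstance_spec" in d:
        spec = dict(cfg.circumstance_spec)
        for name, kv in d.pop("circumstance_spec").items():
            spec[name] = CircumstanceSpec(**kv)
        cfg.circumstance_spec = spec
    if "effect_profile" in d:
        prof = dict(cfg.effect_profile)
        for name, kv in d.pop("effect_profile").items():
            prof[name] = AgeProfile(**kv)
        cfg.effect_profile = prof
    if "intercept_profile" in d:
        cfg.intercept_profile = AgeProfile(**d.pop("intercept_profile"))
    if "household" in d:
        cfg.household = HouseholdSpec(**d.pop("household"))
    if "cohort_bounds" in d:
        cfg.cohort_bounds = _as_tuple_pairs(d.pop("cohort_bounds"))
    for key in ("cohort_shift", "cohort_effect_scale"):
        if key in d:
            v = d.pop(key)
            setattr(cfg, key, None if v is None else tuple(float(x) for x in v))
    if "countries" in d:
        cfg.countries = tuple(str(c) for c in d.pop("countries"))
    if "age_grid" in d:
        cfg.age_grid = tuple(int(a) for a in d.pop("age_grid"))
    for key, val in d.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown generator config key {key!r}")
        setattr(cfg, key, val)
    cfg.validate()
    return cfg


def study_from_dict(d: dict) -> StudyConfig:
    cfg = StudyConfig()
    d = dict(d or {})
    if "cohort_partition" in d:
        v = d.pop("cohort_partition")
        cfg.cohort_partition = v if isinstance(v, str) else _as_tuple_pairs(v)
    if "age_grid" in d:
        cfg.age_grid = tuple(int(a) for a in d.pop("age_grid"))
    if "grouping" in d:
        cfg.grouping = {k: list(v) for k, v in d.pop("grouping").items()}
    if "checks" in d:
        cfg.checks = CellChecks(**d.pop("checks"))
    if "age_cap" in d:
        v = d.pop("age_cap")
        cfg.age_cap = ({int(k): int(a) for k, a in v.items()}
                       if isinstance(v, dict) else v)
    for key, val in d.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown study config key {key!r}")
        setattr(cfg, key, val)
    cfg.validate()
    return cfg


def load_config(path) -> tuple[GeneratorConfig, StudyConfig]:
    """Read a YAML config file into (GeneratorConfig, StudyConfig)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - {"generator", "study"}
    if unknown:
        raise ValueError(f"unknown config sections {sorted(unknown)}")
    return (generator_from_dict(raw.get("generator")),
            study_from_dict(raw.get("study")))
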