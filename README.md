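# iop-lifecycle

Ex-ante parametric measurement of **inequality of opportunity (IOp) in the
prevalence of chronic diseases** over the life cycle and across birth
cohorts, with a Shapley decomposition of the index by circumstance group.

The package is aimed at health economists and life-course epidemiologists
working with retrospective survey microdata (SHARE-style life histories):
individual records carrying childhood circumstances — adverse childhood
experiences (physical harm, quality of the parent–child relationship),
socio-economic background (financial hardship, parental education, absent
parent, household size), gender and childhood health — together with the
number of chronic conditions reported by each age of a 25–65 grid.  Because
such microdata are access-restricted, the package ships a synthetic-data
generator that emulates the schema and its statistical structure, so the
full pipeline is runnable and testable out of the box.

## Method

For each country × birth-cohort × age cell, estimate the reduced-form logit

P(yᵢ = 1) = exp(rᵢ)/(1 + exp(rᵢ)),  rᵢ = α + β·CIᵢ,

where yᵢ indicates at least one chronic condition by that age (or,
alternatively, a condition count at or above the cell median) and CIᵢ is the
circumstance vector.  Replacing each outcome by its fitted probability ŷᵢ
gives the counterfactual distribution, constant within circumstance types;
absolute IOp is the dissimilarity index of that distribution,

D̂ = (1 / 2ȳ) Σᵢ lᵢ |ŷᵢ − ȳ|,  lᵢ = 1/n,  ȳ = Σᵢ lᵢ ŷᵢ,

the minimum share of favourable outcomes that would have to be reallocated
across types to equalise opportunity (0 = equal opportunity; bounded by 1;
a lower bound on total IOp since only observed circumstances enter).  The
contribution of each circumstance group c is its Shapley value relative to
the full index,

RC_c = Σ_{S ∋ c} [(N−M)! (M−1)! / N!] · [D̂(S) − D̂(S∖{c})] / D̂(CI),

where D̂(S) re-estimates the logit with only the circumstances in coalition
S and M = |S|; shares sum to 1 by construction.

## Worked example

```python
import iop_lifecycle as il

cfg = il.default_config(n_per_cell=2000, countries=("AT",),
                        cohort_bounds=((1940, 1945),), seed=7)
panel = il.generate_panel(cfg)
coded, report = il.code_panel(panel)
coded[["outcome_any", "outcome_ge_median"]] = il.build_outcomes(coded, 55)
res = il.estimate_cell(coded, "outcome_any", il.CIRCUMSTANCES,
                       cell=("AT", "1940-45", 55))
print(res.summary())
print(res.shapley(il.DEFAULT_GROUPING).summary())
```

```
Inequality of opportunity — cell estimate
=============================================
cell:        ('AT', '1940-45', 55)
n:           2000
mean yhat:   0.6025
D index:     0.0785
reliable:    True
converged:   True   separation: False
---------------------------------------------
term                        coef        se
intercept                -0.0558          
harm                      0.8363    0.1329
relationship_bad          0.2480    0.1686
gender_female             0.0864    0.0941
parent_absent             0.2719    0.1564
financial_hardship        0.5996    0.1166
parent_tertiary          -0.2494    0.1282
household_size            0.0211    0.0297
child_bad_health          0.4931    0.1813

Shapley decomposition of the dissimilarity index
================================================
cell:    ('AT', '1940-45', 55)
D(full): 0.0785    method: exact
------------------------------------------------
player                     share   share %
ACE                       0.4542     45.4%
SES                       0.4160     41.6%
GENDER                    0.0226      2.3%
CHILD_HEALTH              0.1072     10.7%
------------------------------------------------
total                     1.0000    100.0%
```

By age 55, 60.2 % of this synthetic cohort reports at least one chronic
condition.  The D index of 0.079 says that 7.9 % of the favourable
("healthy") outcomes would need to be redistributed across circumstance
types to equalise opportunity; adverse childhood experiences account for
45 % of that inequality and socio-economic background for 42 %, with
demographics playing a minor role — the ranking the method is designed to
surface.

## Full study runs

The `iop-lifecycle` command orchestrates the whole grid from a YAML config:

```sh
iop-lifecycle simulate  --config study.yaml --out out/    # panel.csv
iop-lifecycle run-all   --config study.yaml --out out/    # results.csv,
                                        # shares.csv, summary_<view>.csv
```

`results.csv` has one row per (country, cohort, age, stratum) cell with the
cell's D index, reliability flag and per-player shares; cells that cannot be
estimated are kept with a reason code.  Summary views reproduce the study's
reporting formats: D-by-age curves per country × cohort, cross-country mean
group shares by cohort × age (in percent), and per-country share bars at
ages 30/40/50/60.

The panel CSV schema (one row per respondent): `id`, `country`,
`birth_year`, `gender`, the raw ordinal responses `harm_parent`,
`harm_other`, `parent_understood`, `relationship_rating`, `child_sah`,
`family_finance`, the booleans `parent_tertiary`, `parent_absent`, the count
`household_size`, and wide disease-count columns `dis_count_25` …
`dis_count_65`.

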