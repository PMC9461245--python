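# Methods

## The estimand and the estimator

Inequality of opportunity (IOp) is the part of health inequality traceable
to *circumstances* — characteristics fixed before any individual choice:
childhood abuse and the quality of the parent–child relationship, family
finances, parental education, an absent parent, household size, gender, and
health in childhood.  The ex-ante parametric approach measures it in three
steps within each country × birth-cohort × age cell:

1. **Reduced-form logit.**  The binary outcome (at least one chronic
   condition reported by the given age; alternatively a condition count at
   or above the cell median) is regressed on the circumstance vector by
   maximum likelihood.  The coefficients absorb both direct effects and
   effects mediated by later choices; nothing here is causal — the model is
   a device for constructing outcome *prospects* by circumstance type.
2. **Counterfactual distribution.**  Each observed outcome is replaced by
   its fitted probability.  Predictions are identical for individuals with
   identical circumstances, so the predicted distribution varies only
   across circumstance types.
3. **Dissimilarity index.**  D = (1/2ȳ) Σ lᵢ|ŷᵢ − ȳ| with uniform weights
   lᵢ = 1/n.  D is the minimum fraction of favourable outcomes that must be
   reallocated across types to equalise prospects; it is 0 iff all
   predictions coincide and cannot exceed 1.  Computing it at the
   individual level with uniform weights or at the type level with type
   population shares is exactly equivalent (predictions are constant within
   type); the package computes at individual level and tests the
   equivalence to 1e-12.

Because only observed circumstances enter, D estimates a *lower bound* on
total IOp: enlarging the circumstance set can only (weakly) raise it.  The
suite asserts this one-sidedly across 20 seeds rather than per draw, since
any single comparison carries Monte-Carlo noise.

**Shapley decomposition.**  The contribution of a circumstance group
("player") is its average marginal contribution to D over all orders of
inclusion; dividing by the full-model D gives relative contributions that
sum to 1 (efficiency).  Two formulations coincide: the subset-weighted sum
with weight (N−M)!(M−1)!/N! per coalition of size M, and the average over
all N! orderings; the package implements the former and tests equality with
the latter to 1e-10.  Each coalition value D(S) comes from a *re-estimated*
logit restricted to S's circumstances — the standard convention, rather
than zeroing coefficients of the full fit — and the empty coalition has
D(∅) = 0 exactly (intercept-only model).  Individual shares may be
negative (marginals are signed); efficiency still holds.  Shares are not
invariant to the coalition structure: splitting a group into two players
and summing their shares approximates, but does not exactly equal, the
merged player's share.  The full-model D, by contrast, is identical across
all partitions of the same circumstance set, which is how the package
operationalises robustness to multicollinearity among circumstances.

## Survey coding rules

Raw responses are recoded exactly as the analysis defines them: `harm` = 1
if physical abuse from a parent *or* anyone else was reported "Often" or
"Sometimes"; `relationship_bad` = 1 for a parent-relationship rating of
"Fair" or "Poor" (the parental-understanding question is deliberately
excluded — it is nearly collinear with the rating and only one of the two
is kept); `financial_hardship` = 1 for families reported poor;
`child_bad_health` = 1 for childhood self-assessed health fair or poor;
`household_size` stays a small-integer covariate (no published cut-off
exists to binarise it).  The median-comorbidity outcome uses the *lower*
median (inverted-CDF quantile), making the "count ≥ median" rule
unambiguous for even cell sizes; an all-zero-count cell then trivially
marks everyone 1 and is caught downstream as degenerate.  Missing or
unrecognised values cause listwise deletion with per-field counts — the
coding never imputes.

## The synthetic-data generator

The generator exists so the full pipeline can be exercised without
restricted survey microdata.  It emulates:

* **Correlated circumstances** via a one-factor Gaussian copula: one shared
  standard-normal factor per individual; each circumstance thresholds
  `loading·factor + √(1−loading²)·noise` at the quantile of its target
  prevalence.  Default prevalences (harm 0.20, bad relationship 0.10,
  financial hardship 0.25, absent parent 0.12, parental tertiary education
  0.15, bad childhood health 0.08, female 0.50) and loadings (0.3–0.5 on
  the adversities, negative for the protective education flag, 0 for
  gender) are in the range typical of retrospective ageing surveys.
  Household size maps its latent through a Poisson quantile
  (2 + Poisson(2.5)), since a single threshold cannot produce a count.
* **An age-indexed disease process**: at each grid age a new condition
  occurs with probability logistic(intercept(a) + cohort shift +
  Σ effect_c(a)·x_c) and counts accumulate, so they are monotone in age by
  construction and both outcome variants derive from one process.  Effects
  are linear in age (log-odds at age 25 plus a per-decade slope); with a
  single grid age the data-generating process *is* the fitted logit, which
  is how parameter recovery is tested (each coefficient within 3 SE at
  n = 10⁴).
* **Cohort differences** through an additive intercept shift and/or a
  per-cohort multiplier on the effect profiles (both default to neutral).

Raw ordinal responses are expanded from the coded binaries with fixed
conditional category probabilities, so re-coding a generated panel
recovers the generated binaries exactly.  Reproducibility is per cell: each
country × cohort draws from a stream keyed by a CRC-32 hash of its label
under the master seed, so adding a country never perturbs existing cells.

What the generator does **not** emulate: survey design (clustering,
calibration weights), item non-response patterns, mortality/attrition
selection (plausible in real data, where respondents with the worst
circumstances die before interview; no functional form is published, so
none is guessed), reporting heterogeneity across cohorts, and country-level
heterogeneity beyond independent sampling streams.  Passing tests therefore
demonstrate correctness of the estimator and pipeline machinery, not
substantive cross-country findings.

### Named scenarios

* `null_config()` — circumstances carry zero effect.  Population D is 0 at
  every age; the estimate is small-positive (the index is non-negative, so
  its null sampling distribution sits above 0).  At n = 5000 with eight
  circumstances the null D stays below 0.05.
* `cumulative_advantage_config()` — flat baseline hazard (log-odds −3.9
  per age step) with effects that start small (0.05) and grow by 0.45
  log-odds per decade on the main adversities.  The population D-by-age
  curve rises monotonically from ≈0.03 at 25 to ≈0.29 at 65.  The default
  cell size of 50 000 keeps the small-sample upward bias of D at young ages
  (few cases, eight covariates) well below the true age-to-age increments,
  so estimated curves are monotone too, not just in expectation.  Adding a
  per-cohort effect multiplier of 1.3 for the two younger cohorts separates
  their curves upward at ages past 50 — the cohort-divergence pattern.

## Numerical conventions

* Logit: statsmodels Newton MLE, relative tolerance 1e-8, 100 iterations.
  Constant columns are dropped (and recorded) before fitting;
  rank-deficiency afterwards raises an error naming the collinear columns
  (identified by pivoted QR).  On perfect separation Newton fails; the fit
  is retried with BFGS and flagged.  A separation flag is also set when any
  fitted probability is within 1e-8 of 0 or 1 alongside a coefficient
  exceeding 10 in magnitude.  No penalisation by default — an optional
  ridge (L2) fit exists but is off, keeping the estimator faithful to plain
  maximum likelihood.
* Coalition fits inside the Shapley loop that are unusable (separation,
  non-convergence, collinearity within the subset) fall back to within-type
  empirical outcome means — the saturated nonparametric counterpart — so a
  single ill-behaved coalition cannot poison all 2^N terms; the fallback is
  logged.  Coalitions are enumerated in a canonical order and values
  memoised per circumstance-column set.
* A constant prediction vector returns D = 0 exactly (short-circuit before
  the floating-point mean introduces 1e-17 residue); ȳ = 0 raises a
  degenerate-cell error (the index is undefined with no favourable mass).
* Cell validity: cells need n ≥ 50 with ≥ 10 cases and ≥ 10 non-cases to be
  flagged reliable (thresholds configurable); below-threshold cells are
  still estimated when mathematically possible but excluded from summary
  averages.  All-case or all-non-case cells are degenerate and reported
  missing-with-reason; in grid runs they never abort the run.
* Age availability: by default a cohort's maximum analysable age is the
  interview year (2017) minus its last birth year, floored to the grid;
  explicit per-cohort caps can override this, and synthetic runs typically
  disable the cap (generated data have no observability limit).
* Cross-country summary averages are unweighted country means; shares are
  kept as fractions internally and formatted as percent only in the
  summary layer.

## Problem sizes

The test suite and acceptance script run at deliberately modest scales
chosen to make each property's signal dominate Monte-Carlo noise: exact
identities on cells of 1 500–3 000 records; parameter recovery at 10⁴;
null-bias checks at 5 000; the paired effectful-vs-null comparison at
2 000 × 20 seeds; life-cycle monotonicity on one country × four cohorts ×
nine ages at 50 000 per cell.  The whole suite completes in well under five
minutes on one CPU.

## Known limitations

* The dissimilarity index is biased upward in small cells (it is a
  non-negative functional of noisy predictions); the package reports and
  flags rather than bias-corrects.  Comparisons of D across cells of very
  different sizes should be read with this in mind.
* No uncertainty intervals for D or shares are produced; a bootstrap is a
  natural extension but is not part of the estimator as specified.
* The sampling Shapley path reports Monte-Carlo standard errors per player,
  but with the default four players exact enumeration (16 coalitions) is
  always preferable.
* Gender-stratified runs drop gender from the circumstance set and the
  grouping; stratified and pooled shares are therefore not directly
  comparable player-by-player.
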