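# Methods

This note records the statistical procedures implemented in frailtykit, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data generator does and does not emulate.

## Frailty index

The index is the deficit-accumulation construction: 30 dichotomous items, each
coded 0 (no deficit), 1 (deficit) or missing, and

FI = n_deficits / denominator.

Two denominator policies are provided. `"observed"` (the default, standard
deficit-accumulation practice) divides by the number of items actually
observed, and declares the index undefined when fewer than
`min_observed_fraction` (default 0.8, i.e. 24 of 30) items are observed —
undefined subjects are counted and reported, never silently dropped.
`"fixed"` always divides by the catalogue size. For complete records the two
coincide and FI·30 is an integer in [0, 30].

The shipped 30-item catalogue (5 comorbidities, 9 basic-ADL items, 6
instrumental-ADL items, falls, depressive mood, three-word recall,
serial-seven subtraction, low grip strength, poor self-rated health, hearing
problem, dental problem, abnormal BMI, low quality of life) is a documented
default reconstructed from the domain composition typical of 30-item indices
in this literature. Every analysis takes the schema as an input, so studies
with a different item battery bind their own YAML schema and column mapping.

Severity intervals are closed on the right: with boundaries (c1, c2, c3) the
categories are [0, c1], (c1, c2], (c2, c3], (c3, 1]. An FI of exactly 0
belongs to the lowest category, and an FI exactly on a boundary to the less
severe side. The same convention places subjects on stratum boundaries into
the lower stratum during stratification, so stratum counts always tile the
cohort.

## Stratum-specific likelihood ratios and cutpoint derivation

For stratum s, SSLR_s = (x1_s/n1)/(x0_s/n0) with x1_s/x0_s the deaths and
survivors inside the stratum and n1/n0 the cohort totals. The confidence
interval is the log-scale Wald interval for a likelihood ratio (Simel-type):

SE(ln SSLR) = sqrt(1/x1 − 1/n1 + 1/x0 − 1/n0),
CI = exp(ln SSLR ± z_{1−α/2}·SE).

A stratum with a zero cell receives the Haldane–Anscombe correction (0.5
added to both stratum cells, 1 to both totals) and is flagged.

Adjacent strata are compared by a two-sided z-test on the difference of log
SSLRs, treating the strata as independent (the shared overall denominators
induce a covariance that is ignored; with stratum counts small relative to
the totals the effect is negligible). The merge scan runs left to right over
the original, unmerged strata: the boundary between strata k−1 and k is kept
iff the test gives p < α (default 0.05, no multiplicity adjustment — one
decision per boundary, mirroring the way such tables are read). A
`recompute_after_merge` mode instead compares each stratum against the
running merged group. Groups are labelled fit / pre-frail / mildly-frail /
severely-frail in increasing order; with more than four groups the extras get
numbered labels.

Two identities are useful checks and are enforced in the test suite: the
survivor-weighted average of the SSLRs over any full stratification is
exactly 1 (Σ_s (x0_s/n0)·SSLR_s = Σ_s x1_s/n1 = 1), and merging everything
into one stratum gives SSLR = 1 with a CI containing 1.

Default candidate boundaries are {0.03, 0.10, 0.25, 0.30, 0.33, 0.45} —
values commonly proposed for deficit-accumulation indices; they are a config
parameter, and pre-tabulated counts tables (columns lower, upper, died,
survived) can be fed directly so published stratifications are reproducible
without microdata.

## Survival validation

*Person-time rates* are events per summed follow-up, scaled per 1,000
person-years, with exact Poisson (chi-square) intervals.

*Kaplan–Meier* curves come from lifelines, one fit per severity group.

*Cox proportional-hazards models* are fitted by statsmodels' PHReg. Tie
handling defaults to Breslow — the convention of the major commercial survival
stacks, so coefficients are comparable with published tables — with Efron
selectable. Severity-category indicators are expressed against the fittest
group; covariates (age in years as a continuous linear term, smoking, wealth
quintile) enter linearly. Non-convergence and monotone likelihood
(separation, detected from runaway coefficients or exploding standard
errors) set `converged=False` on the result instead of failing silently.
Constant covariates and fewer than two distinct event times are hard errors.
Subgroup tables refit the same formula per stratum of a grouping variable
(e.g. gender, caretaker availability), skipping and flagging strata that
cannot support a fit.

*Harrell's C* uses scikit-survival's censored pair counting: a pair is
comparable when the earlier observed time is an event; tied risk scores count
1/2. The test suite holds this equal to an exhaustive O(n²) enumeration.
Two risk scores are compared by a paired bootstrap (default 1,000 resamples,
seeded): subjects are resampled with replacement, both C-indices recomputed,
and H0: ΔC = 0 tested with a normal approximation on the bootstrap SE of the
difference. The bootstrap was chosen as a distribution-free default; other
variance estimators for C differences exist and none is canonical.

## Wealth index

The classic Filmer–Pritchett/DHS construction: column-standardise the binary
asset indicators by sample mean and SD, take the first principal component,
and orient it so that owning more assets raises the score (sign fixed by the
correlation with the asset count). Constant columns are dropped with a
warning; at least two informative columns are required. Quintiles cut at the
20/40/60/80th percentiles, with boundary ties assigned to the lower (poorer)
quintile, deterministically; quintile 1 is the poorest.

## Synthetic cohorts

The generator emulates the statistical structure of a national
health-examination survey of community-dwelling older adults followed for
mortality:

- **Ages** truncated-normal: mean 69.2, SD 6.8, truncated at 60 (the observed
  mean after truncation is ≈ 70.3). 50.8% women.
- **Deficits**: each item is Bernoulli with logit = intercept_j +
  0.03·(age − 60) + 0.25·female + liability, where the per-subject liability
  is N(0, 0.30²) plus, with probability 0.015, a +2.2 shift representing a
  small severely-impaired subpopulation. The single shared liability is the
  simplest structure that makes deficits co-occur across domains and skews
  the FI distribution to the right; the mixture component supplies the heavy
  severe tail that a symmetric liability cannot. Item intercepts are solved
  at generation time (Gauss–Hermite quadrature + Brent root-finding) so each
  item's *marginal* prevalence matches its configured target, keeping the
  configuration in interpretable prevalence units.
- **Calibration**: the default item-prevalence vector, liability SD, age
  slope and mixture parameters were tuned once against the published
  severity mix of such cohorts (≈26/57/16/1% across fit/pre-frail/mildly
  frail/severely frail, frailty more prevalent in women, mean FI rising with
  age decade) and then frozen. They are study conditions, not free knobs.
- **Mortality** is exponential conditional on severity: hazard = 0.0151/yr ×
  (1, 1.76, 2.79, 6.34) by true category, so the fit group's death rate is
  15.1 per 1,000 person-years in closed form and the cohort-average rate is
  ≈27/1,000 py. An optional per-category caretaker multiplier supports
  interaction experiments. Censoring is administrative at 7 years minus a
  uniform 1-year entry offset (entry dates of a one-year field survey against
  a fixed registry cut-off).
- **Covariates**: caretaker availability is Bernoulli by true category
  (28.1/36.0/48.2/66.0%), smoking by gender (70%/33%), and a 10-asset battery
  is driven by a wealth latent correlated −0.35 with the frailty liability,
  so wealthier subjects are fitter on average. These are generated
  conditionally on severity to reproduce observed gradients; no causal
  structure is claimed.
- Ground truth (liability, true category, true hazard, uncensored event time)
  is returned separately from the observed table, and the same seed yields a
  byte-identical cohort.

What the generator does **not** emulate: multistage cluster sampling and
survey weights, item-level missingness patterns, longitudinal deficit
trajectories, non-constant baseline hazards (a Weibull option would be the
natural extension), and competing risks. Passing tests on synthetic cohorts
therefore demonstrate that the estimators recover known generating values
under a clean proportional-hazards world — not that any particular real
survey satisfies those assumptions.

## Parameter recovery

`recovery_experiment` repeats per replicate: simulate → score → derive
cutpoints (recorded) → Cox refit of the category indicators, with categories
taken at the generating boundaries so the refit estimand equals the
generating log-hazard ratios (the derived cutpoints are reported as a
distribution but not used for the refit, which would change the estimand).
The report aggregates bias, RMSE and Wald 95% CI coverage per category
log-HR and collects per-replicate failures without aborting the batch. At
the default conditions (200 replicates of n = 8,000) coverage sits in the
nominal band and the derived boundaries coincide with the generating
{0.10, 0.25, 0.45} in ≈95% of replicates.

## Numerical conventions

- Boundary and tie conventions: right-closed severity intervals; boundary FI
  values to the lower stratum; wealth-score boundary ties to the poorer
  quintile; risk-score ties in C count 1/2.
- All randomness flows from explicit integer seeds; child seeds are derived
  with numpy's SeedSequence. Simulation without a seed is an error.
- Reports print full precision; display rounding to 2 decimals matches the
  convention of published severity tables.
- The default test size α = 0.05 applies to both the adjacent-stratum test
  and all Wald intervals; both are configurable per call.

## Known limitations

- The adjacent-stratum z-test ignores the covariance induced by shared
  totals and the multiplicity of the six boundary decisions; it reproduces
  the published decision pattern but is not a calibrated simultaneous test.
- PHReg offers no robust (sandwich) variance here; CIs are model-based Wald.
- The default deficit schema is a stand-in battery: analyses of a real survey
  should supply the instrument's own item definitions.
- The C-index comparison p-value depends on the bootstrap scheme; with very
  few events the normal approximation on the bootstrap SE is rough.
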