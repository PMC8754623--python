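# Methods

This document records the statistical methodology and the numerical choices
implemented in `nutridecomp`, with enough detail that every reported number
can be derived independently.

## 1. Outcome definition

Child nutritional status is classified from the weight-for-age Z-score (WAZ)
with strict thresholds:

- `waz < -2` → underweight,
- `waz < -3` → severely underweight (a subset of underweight),
- `waz >= -2` → not underweight.

The boundary value `-2.0` exactly is classified as *not* underweight (strict
inequality).  `classify_waz` and the CSV reader both apply this rule, so an
input file carrying only `waz` yields the same indicator as one carrying a
precomputed `underweight` column derived the same way; inconsistent pairs are
rejected at load time.

## 2. Survey-weighted logistic model

For each survey `s` with observations `(y_i, x_i, w_i)` — binary outcome,
design row, sampling weight — the coefficient vector `β_s` maximizes the
weighted log-likelihood

```
ℓ(β) = Σ_i w_i [ y_i log F(x_i'β) + (1 − y_i) log(1 − F(x_i'β)) ],
```

with `F` the logistic CDF.  Design rows consist of an intercept followed by
reference-omitted dummy columns for each categorical variable, in schema
order.  Weights enter as survey (probability) weights: the point estimate is
invariant to rescaling all weights by a constant, and coincides with the
frequency-weighted estimate when weights are integers.

Properties used downstream:

- the weighted score equations imply
  `Σ_i w_i F(x_i'β̂) / Σ_i w_i = Σ_i w_i y_i / Σ_i w_i`,
  i.e. the fitted model reproduces each survey's weighted prevalence exactly
  (the intercept column's score equation); this is what makes the
  decomposition in §3 additive without a residual term;
- the default covariance is the sandwich
  `H⁻¹ (Σ_i w_i² s_i s_i') H⁻¹` with `H` the observed information and `s_i`
  the per-observation score, appropriate for probability weights; `model`
  (inverse information) and `cluster` (scores summed within clusters before
  the outer product) variants are available.

### Numerical scheme

Newton–Raphson with:

- start value: intercept at `logit` of the weighted prevalence, slopes 0;
- convergence: max-norm of the score below `1e-8` (at most 100 iterations,
  else `ConvergenceError`);
- step-halving (at most 10 halvings) whenever a full step fails to improve
  the log-likelihood; "improve" is judged with a relative slack of
  `1e-9 · (1 + |ℓ|)`, because at large n the weighted log-likelihood is a
  large-magnitude sum whose floating-point rounding error exceeds any fixed
  absolute tolerance near the optimum;
- separation guard: any `|β_j| > 30` during iteration raises
  `SeparationError` (at that magnitude fitted probabilities are within
  ~1e-13 of 0/1 and the MLE is divergent);
- a singular information matrix raises `CollinearityError`.

Estimates are verified in the test suite against an independent IRLS
implementation (statsmodels `GLM` with frequency weights) to `1e-6`.

## 3. Decomposition on the probability scale

Let `B` be the baseline survey and `A` the comparison survey, with weighted
means `mean_s[·]` taken over survey `s`'s observations.  The change in
prevalence decomposes as

```
p̄_A − p̄_B = E + C,
E = mean_A[F(x'β_A)] − mean_B[F(x'β_A)]        (endowments / composition)
C = mean_B[F(x'β_A)] − mean_B[F(x'β_B)]        (coefficients / returns)
```

`E` holds coefficients fixed at the comparison survey's and varies the
covariate distribution; `C` holds the baseline covariate distribution fixed
and varies the coefficients.  Because the fitted models reproduce their own
weighted prevalences (§2), `mean_A[F(x'β_A)] = p̄_A` and
`mean_B[F(x'β_B)] = p̄_B`, so the identity is exact, not approximate — the
test suite asserts it to `1e-10` on arbitrary inputs.

The decomposition is stated on the *probability* scale (differences of mean
predicted probabilities), not the linear-predictor scale: components are then
directly interpretable as percentage-point contributions to the prevalence
change, and the total telescopes to the observed change without a link-scale
residual.  The cost is path dependence: the counterfactual `mean_B[F(x'β_A)]`
is one of two natural orderings.  The implemented convention evaluates
endowments at the comparison survey's coefficients and coefficients at the
baseline composition; swapping the roles of `A` and `B` negates the total
and permutes the components in the way the tests document.

### Detailed (per-covariate) contributions

Totals are attributed to covariates by linearizing the index.  With
`x̄_s` the weighted design-column means of survey `s`:

```
E_k = E ·  (x̄_A,k − x̄_B,k) β_A,k  /  Σ_j (x̄_A,j − x̄_B,j) β_A,j
C_k = C ·  x̄_B,k (β_A,k − β_B,k)  /  Σ_j x̄_B,j (β_A,j − β_B,j)
```

where for `C` the sum includes the intercept (`x̄_·,0 = 1`), reported as the
`Constant` row; the intercept contributes nothing to `E` since its "mean"
does not differ between surveys.  By construction `Σ_k E_k = E` and
`Σ_k C_k = C` whenever the linearization denominators are nonzero; a
denominator within `1e-12` of zero while the corresponding component exceeds
`1e-10` raises `DegenerateAllocationError` rather than returning arbitrary
allocations (the component is real but cannot be attributed linearly).

Percentage shares are reported relative to the *grand total* `E + C`:
`pct(term) = 100 · term / (E + C)`, so all detailed rows plus the `Constant`
row sum to 100%.  A zero grand total makes shares undefined
(`UndefinedPercentageError` from `pct_contribution`; `NaN` in tables).

### Reference-category normalization

Dummy coding makes detailed categorical contributions depend on which
category is the reference.  The implemented remedy is the deviation-from-means
transform: for a variable with `m` categories, coefficients are mapped to an
expanded set with one coefficient per category (including the reference,
whose dummy coefficient is 0) and the constraint that the `m` expanded
coefficients sum to zero; the intercept absorbs the mean effect.  The map is
linear, `β_exp = T β`, so the expanded covariance is `T V T'` and the
delta-method machinery applies unchanged.  Expanded design-column means are
the weighted category shares (the reference share being one minus the sum of
the dummy means).

Under this normalization the per-category detailed terms are invariant to
the reference-category choice.  The linearization denominators are invariant
even without normalization (they are weighted sums of predicted-index
differences, which do not depend on the coding); the tests verify full
invariance of the normalized detail by refitting under every possible
reference assignment.  Normalization is on by default
(`detailed_decompose(..., normalize=True)`).

## 4. Variance estimation

Two sources of sampling variation enter `E` and `C`: the estimated
coefficients `(β̂_A, β̂_B)` and the empirical covariate distributions (the
weighted means of `F` over the observed samples).

**Component totals (default).**  Reported standard errors for `E` and `C`
use influence functions that include both sources.  For a statistic
`θ = mean_s[F(x'β)]`, each observation in survey `s` contributes a
composition term `(w_i/Σw)(F(x_i'β) − θ)`, and each observation in the
survey that estimated `β` contributes a coefficient term obtained by solving
the information matrix against its weighted score and propagating through
the analytic gradient `∂θ/∂β = mean_s[f(x'β) x]` (`f` the logistic density).
Surveys are independent, so variances add across surveys.  This is the
default (`composition_variance=True`) because conditioning on the observed
covariate composition materially understates the unconditional variance of
`E` — in the shipped scenario the coefficient-only standard error of `E` is
about two thirds of the bootstrap value, while the influence-function
version matches a 500-replicate nonparametric bootstrap within a few percent
for both components (asserted in the test suite).

**Conditional (coefficient-only) variant.**  `delta_se` with its default
`include_composition=False` treats the design means as fixed and propagates
only `cov(β̂_A)` and `cov(β̂_B)` (block-diagonal across surveys) through the
analytic gradients of `E` and `C`.  This conditional variance is retained
because it answers a different question (uncertainty given the observed
composition) and has clean diagnostic properties: with zero coefficient
covariances it is exactly zero, and `∂E/∂β_B = 0`.

**Detailed terms.**  Standard errors for per-covariate terms propagate the
coefficient covariances through a finite-difference Jacobian of the full
detail vector (central differences, step `1e-6`), on the expanded scale when
normalization is on.  Confidence intervals are `estimate ± 1.959964 · se`.

## 5. Stratified trends and phase differences

`weighted_prevalence` returns prevalences in percent, overall or by the
categories of a stratifying variable; an empty stratum yields `NaN` (logged,
not an error).  `build_trend_table` assembles these across any number of
surveys, and `phase_differences` appends `later−earlier` columns for
requested survey pairs (e.g. `2016-2005`).  Differences are plain
percentage-point subtractions, so consecutive phase differences sum to the
full-period difference exactly; a pair naming an absent survey raises an
error naming it.  The overall decomposition total (×100) equals the overall
trend difference for the same survey pair — an end-to-end identity the
pipeline tests assert.

## 6. Synthetic generator and exact ground truth

`GeneratorConfig` specifies, per survey: category probabilities for each
schema variable (drawn independently across variables), a coefficient vector
on the dummy-coded scale, a weight model, and an outcome mode:

- `binary-direct`: `y ~ Bernoulli(F(x'β))`;
- `waz-latent`: a latent WAZ is drawn as
  `waz = μ(x) + σ·z`, `z ~ N(0,1)`, with
  `μ(x) = −2 − σ·Φ⁻¹(F(x'β))` so that `P(waz < −2 | x) = F(x'β)` exactly;
  the indicator is then derived by thresholding.  This exercises the full
  WAZ-classification path while keeping the same logistic ground truth.

Weights are log-normal with unit mean (`σ_log = 0.5` by default), drawn
independently of covariates and outcome, so weighted and unweighted
population targets coincide and weighting machinery can be tested for
invariance.  Randomness is fully determined by `(seed, survey_index)` via
independent `numpy` substreams `default_rng([seed, survey_index])`, so
surveys are reproducible individually and adding a survey never perturbs
earlier ones.

Because covariates are independent categoricals, the covariate space is a
finite product of category sets and the population quantities

```
p_s = Σ_cells P_s(cell) F(x_cell'β_s),   E_true, C_true  (same formulas as §3)
```

are computed by *exact enumeration* (capped at 10⁶ cells; larger spaces are
rejected rather than approximated).  `E_true + C_true` equals the population
prevalence difference identically, and estimator consistency is tested by
checking recovery of these enumerated values within reported standard errors.

### Shipped default scenario

`default_config()` defines three surveys ("2005", "2011", "2016"), six
categorical covariates (maternal education ×3, wealth ×3, residence ×2,
birth size ×2, breastfeeding ×3, maternal age ×3; 324 cells), compositions
shifting toward more education, wealth and urban residence over time, and
per-survey coefficient vectors with plausible signs (education and wealth
protective, small-at-birth harmful).  The three intercepts were calibrated
once, by root-finding on the enumerated population prevalence, so that the
scenario sits at survey-level prevalence anchors of 38%, 29% and 24%; the
calibrated values (−0.4239, −0.7255, −0.6813) are frozen constants.  The
resulting population decomposition for 2005→2016 is
`E_true = −0.014496`, `C_true = −0.125511` (shares 10.35% / 89.65% of the
total change of −0.140007).

Default problem sizes in examples and the acceptance script
(`n_per_survey = 8000`) are the package's own choice: large enough that a
single draw lands within a few tenths of a percentage point of the anchors,
small enough that every end-to-end run completes in seconds.

## 7. Limitations

- The generator draws covariates independently within survey; real surveys
  have correlated covariates (wealth and residence, say).  The decomposition
  code does not rely on independence — only the *exact* ground-truth
  enumeration does.
- No cluster/stratum sampling design is simulated; weights are noise
  independent of everything.  Cluster-robust covariance is implemented but
  exercised only on synthetic cluster labels.
- The linearized detail is a first-order attribution; alternative detailed
  weighting schemes exist and give different per-covariate splits (the
  totals are unaffected).
- The probability-scale decomposition is path dependent (§3); results are
  reported for one stated ordering.
- Detailed-term standard errors condition on the observed composition;
  only the component totals carry the full influence-function variance.
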