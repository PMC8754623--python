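# nutridecomp

Survey-weighted trend analysis and nonlinear Blinder–Oaxaca decomposition of
change in child underweight prevalence between household survey rounds.

## The problem

Repeated cross-sectional household surveys (DHS-style) record, for each child,
a weight-for-age Z-score (WAZ), a sampling weight, and household/maternal
covariates.  Underweight is `WAZ < -2`.  Between two survey rounds the
underweight prevalence changes; the question is *why*: how much of the change
is explained by shifts in population composition (more educated mothers,
richer households, …) and how much by changes in the covariate–outcome
relationship itself?

`nutridecomp` answers this with a decomposition on the probability scale.
For each survey a survey-weighted logistic regression is fitted,

```
P(underweight = 1 | x) = F(x'β),     F(t) = 1 / (1 + exp(-t)),
```

and the change in prevalence between a baseline survey *B* and a comparison
survey *A* is split exactly into two parts:

```
p̄_A − p̄_B =  [ mean_A F(x'β_A) − mean_B F(x'β_A) ]   (E, endowments / composition)
           + [ mean_B F(x'β_A) − mean_B F(x'β_B) ]   (C, coefficients / returns)
```

where `mean_s` is the sampling-weight-weighted mean over survey *s*'s
observations.  Because the fitted weighted logit reproduces each survey's
weighted prevalence, `E + C` equals the observed prevalence change exactly.

Each component is further attributed to individual covariates via a
linearization of the index function, with an optional deviation-from-means
("reference-invariant") normalization so that detailed contributions of
categorical variables do not depend on the arbitrary choice of reference
category.  Standard errors for totals and detailed terms come from the delta
method; component-total standard errors additionally account for sampling
variation in the covariate composition via influence functions.  See
[docs/methods.md](docs/methods.md) for the full methodology.

The package also produces stratified prevalence trend tables across any
number of survey rounds, with between-round ("phase") difference columns,
and ships a synthetic multi-survey generator whose population decomposition
is known *exactly* by enumeration — used throughout the test suite as ground
truth.

## Quick start (CLI)

Run the full pipeline on the shipped synthetic scenario (three survey rounds
labelled 2005 / 2011 / 2016, six categorical covariates, calibrated to
prevalences of roughly 38%, 29% and 24%):

```
$ nutridecomp run --seed 1 --out demo
overall prevalence (%): 2005=38.10, 2011=28.44, 2016=24.51
decomposition 2005->2016: total=-0.13582  E=-0.01969 (14.50%)  C=-0.11613 (85.50%)
report bundle in demo
```

This writes `trend.csv` (stratified prevalences with phase differences),
`decomposition.csv` (per-covariate detail with standard errors and 95% CIs),
`overall_trend.csv` and `run_log.json` into `demo/`.

Other subcommands:

```
nutridecomp generate  --seed 1 --out data/        # synthetic CSVs + exact ground truth
nutridecomp trends    --config cfg.yaml --out out/
nutridecomp decompose --config cfg.yaml --baseline 2005 --comparison 2016 --out out/
```

A YAML config can point at real survey CSVs instead of the generator:

```yaml
inputs:
  - {path: survey_2005.csv, survey: "2005"}
  - {path: survey_2016.csv, survey: "2016"}
schema:
  - {name: wealth, categories: [Poor, Middle, Rich]}
  - {name: residence, categories: [Urban, Rural]}
decomposition: {baseline: "2005", comparison: "2016"}
```

Input CSVs need the covariate columns, a `weight` column, and either an
`underweight` indicator or a `waz` column (underweight is then derived as
`waz < -2`; rows with missing values are dropped and counted).

## Quick start (API)

```python
from nutridecomp import (
    build_design, default_config, detailed_decompose, fit, generate_survey,
)

cfg = default_config(n_per_survey=8000, seed=1)
data = {s: generate_survey(cfg, i) for i, s in enumerate(cfg.surveys)}

d_B = build_design(data["2005"])
d_A = build_design(data["2016"])
res = detailed_decompose(d_A, d_B, fit(d_A), fit(d_B))

print(f"total={res.total:+.5f}  E={res.E:+.5f} ({res.pct_E:.2f}%)  "
      f"C={res.C:+.5f} ({res.pct_C:.2f}%)")
print(res.to_frame().head(4).to_string(index=False))
```

Output:

```
total=-0.13582  E=-0.01969 (14.50%)  C=-0.11613 (85.50%)
       variable   category         E     E_se  E_ci_low  E_ci_high     E_pct         C     C_se  C_ci_low  C_ci_high      C_pct
women_education       None -0.013373 0.001159 -0.015644  -0.011102  9.846178  0.006995 0.013518 -0.019500   0.033489  -5.149899
women_education    Primary  0.002708 0.001046  0.000658   0.004759 -1.993984  0.003614 0.003265 -0.002786   0.010014  -2.660884
women_education Secondary+ -0.004006 0.000481 -0.004950  -0.003062  2.949428 -0.001230 0.001238 -0.003656   0.001196   0.905492
```

Percentages are shares of the grand total `E + C`, so they sum to 100 across
all rows.  The exact population values for this scenario (by enumeration)
are `E = -0.01450`, `C = -0.12551`; the estimates above are a single draw at
n = 8000 per survey.

## Testing

```
python -m pytest -q tests/
```

The suite (~140 tests, under half a minute) covers: closed-form logistic
fits and agreement with an independent optimizer; exact additivity and path
identities of the decomposition; hand-worked small examples; reference-
category invariance of the normalized detail; delta-method standard errors
cross-checked against finite differences and against a nonparametric
bootstrap; parameter recovery from the generator against enumerated ground
truth; and arithmetic identities of published trend and decomposition tables.

## Layout

```
src/nutridecomp/
  core_data.py       schemas, WAZ classification, CSV I/O, design matrices
  weighted_logit.py  survey-weighted logistic MLE (Newton–Raphson, robust cov)
  decomposition.py   E/C components, detail, normalization, standard errors
  synthetic_data.py  multi-survey generator with exact enumerated ground truth
  pipeline.py        trend tables, phase differences, end-to-end runs
  cli.py             click-based CLI
docs/methods.md      methodology and numerical choices
scripts/acceptance.py
tests/
```
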