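# lungage

Spirometry-derived **lung age**: sex-specific backward-age regression
models, Δ-lung-age normal limits, airflow-limitation staging, propensity
matching, and calibrated synthetic spirometry cohorts.

## The problem

Spirometry reports many parameters (FEV1, FVC, FEF50%, FEF75%, MMEF, …)
that patients find hard to interpret. *Lung age* condenses them into one
intuitive number: the chronological age at which a healthy nonsmoker would,
on average, show the same spirometry. It is estimated *backwards* — healthy
subjects' chronological age is regressed on their spirometry:

```
age ~ β0 + β_h·height + β_50·FEF50% + β_75·FEF75% + ns(FEV1)
```

where `ns(FEV1)` is a natural cubic spline (piecewise cubic, linear beyond
its boundary knots), because lung function declines nonlinearly with age
and a straight line in FEV1 underfits. Three model families are provided —
multiple linear regression (`mlr`), continuous one-breakpoint piecewise
linear regression (`piecewise`), and the natural-spline model (`spline`) —
compared by adjusted R² and validated by subject-level bootstrap.

**Δ lung age** = lung age − chronological age. Positive Δ means lung
function worse than the healthy average for that age. Because healthy Δ
declines with age, the upper limit of normal is age-dependent:

```
ULN(age) = a + b·age + z·RSE          (z = 1.645, one-sided 95%)
```

with a constant alternative (the 95th percentile of healthy Δ). A subject
is `consistent` (Δ ≤ 0), `older_within_uln` (0 < Δ ≤ ULN) or `above_uln`.
COPD/asthma patients are staged I–IV on FEV1%pred (≥80 / 50–79 / 30–49 /
<30) and compared against matched healthy subjects via propensity score
matching on age, height and sex.

The package also ships published reference coefficients: the linear parts
of the sex-specific spline equations (male intercept 2.25, height 0.49,
FEF50% 3.47, FEF75% −8.92; female 28.49 / 0.36 / 4.45 / −12.52 — the
`ns(FEV1)` part was distributed separately and must be supplied to
evaluate them), and the Δ-lung-age limits
`ULN = 12.243 − 0.323·age + 1.645×7.037` (spline) and
`14.690 − 0.392·age + 1.645×7.387` (MLR).

Because no subject-level reference data are distributed, a first-class
synthetic generator emulates the published cohort summary tables (healthy
modelling/validation groups and staged COPD/asthma groups) so the entire
pipeline is testable offline; see `docs/methods.md` for what it does and
does not emulate.

## Worked example

```python
import pandas as pd
from lungage import (LungAgeModel, generate_healthy, generate_patients,
                     compute_delta, derive_age_dependent_uln, classify_delta)

healthy = generate_healthy("healthy_modelling", n=2931, seed=7)
res = LungAgeModel(healthy, "male", method="spline").fit()
print(res.summary())
```

```
Lung age estimation equation (spline, male)
  n = 1379, predictors = 7
  R² = 0.5939   adjusted R² = 0.5918
  RSE = 9.543 years   MSE = 90.54 years²

  term                coef                  95% CI
  intercept         -25.95  (   -46.99,    -4.908)
  height            0.5449  (   0.4254,    0.6644)
  fef50              -1.04  (   -1.538,   -0.5408)
  fef75             -4.461  (   -5.277,    -3.645)
  ns_fev1_1         -22.62  (   -25.05,    -20.19)
  ...
  spline knots: [3.0298, 3.8077, 4.1578, 4.4568, 4.875]
```

The fit explains ~59% of age variance with a residual standard error of
~9.5 years — the natural scale of between-subject lung-function
variability. Deriving the normal limit of Δ lung age from both sexes and
screening a synthetic stage II COPD cohort:

```python
eqs = {s: LungAgeModel(healthy, s, method="spline").fit().equation
       for s in ("male", "female")}
deltas = pd.concat([compute_delta(eqs[s], healthy[healthy.sex == s])
                    for s in ("male", "female")])
uln = derive_age_dependent_uln(deltas["delta"], deltas["age"],
                               constant_percentile=0.95)
copd = generate_patients("copd", "II", n=70, seed=11)
d = pd.concat([compute_delta(eqs[s], copd[copd.sex == s])
               for s in ("male", "female")])
labels = classify_delta(d["delta"].to_numpy(), d["age"].to_numpy(), uln)
```

```
ULN(age) = 15.078 + (-0.398)*age + 1.645*7.305
constant ULN = 15.76 years
stage II COPD mean delta = 17.2 years; above ULN: 65/70
```

A moderate-obstruction cohort averages a lung age ~17 years above its
chronological age, and 65 of 70 subjects exceed the age-dependent ULN —
the qualitative pattern that makes Δ lung age a severity surrogate.

The same pipeline from the shell:

```bash
lungage simulate --profile healthy_modelling --n 2931 --seed 7 --out healthy.csv
lungage fit      --records healthy.csv --method spline --out model.json
lungage uln      --records healthy.csv --model model.json --out model_uln.json
lungage simulate --profile copd_stage_II --n 70 --seed 11 --out copd2.csv
lungage classify --records copd2.csv --model model_uln.json --out classified.csv
lungage stage    --records copd2.csv --out staged.csv
lungage match    --cases copd2.csv --controls healthy.csv --seed 5 \
                 --out-pairs pairs.csv --out-balance balance.csv
```

## Layout

- `lungage.basis` — natural cubic spline basis + truncated-power oracle
- `lungage.model` — `LungAgeModel` → `fit()` → `LungAgeResults`; selection
  by adjusted R²; bootstrap validation
- `lungage.equation` — portable equations, Δ lung age, published coefficients
- `lungage.norms` — ULN derivation, classification, stages I–IV
- `lungage.cohorts` — inclusion filter, propensity matching, SMD
- `lungage.synthetic` — calibrated cohort generator (12 built-in profiles)
- `lungage.io` / `lungage.cli` — CSV/JSON formats and the `lungage` command
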