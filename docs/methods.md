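# Methods

This note documents the models, numerical choices and limitations of
`lungage` in the package's own terms. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Backward-age regression

Lung age is defined by backward prediction: ordinary least squares with the
chronological age of healthy never-smokers (18–80 y) as the response and
spirometry plus height as explanatory variables, fitted separately per sex.
The FEV1 effect enters one of three ways:

- **mlr** — a single linear coefficient.
- **piecewise** — one continuous breakpoint: design columns `fev1` and
  `max(fev1 − c, 0)`, with `c` chosen by minimum residual sum of squares
  over a grid of FEV1 quantiles (5th–95th percentile in 1-percentile steps
  by default, or a user grid). One breakpoint in FEV1 only: FEV1 is the
  variable the spline method also treats nonlinearly, so it is the natural
  candidate; multiple breakpoints are out of scope.
- **spline** — natural cubic spline columns in FEV1. Default knots: 3
  interior knots at the 25th/50th/75th percentiles of the fitting sample's
  FEV1, boundary knots at the 5th/95th percentiles; both count and
  locations are configurable, and externally published knots/coefficients
  can be supplied verbatim. Quantile placement is the standard convention
  when a published spline specification is unavailable.

Fit statistics: R², adjusted R² `1 − (1 − R²)(n − 1)/(n − p − 1)`, residual
standard error `√(RSS/(n − p − 1))` (years) and MSE `RSS/n` (years²);
coefficient intervals are t-based 95%. Model selection maximises adjusted
R²; exact ties resolve to fewer parameters, then to the fixed order
mlr < piecewise < spline, so selection is deterministic. Candidates that
fail (e.g. rank-deficient designs) are skipped and logged, not fatal.

Internal validation resamples subjects with replacement (`B = 1000` by
default), refits, and summarises coefficients and fit statistics across
replicates. For the spline family the primary fit's knots are frozen
across replicates so coefficients are comparable; replicates whose
resample is rank-deficient are skipped and counted.

### Spline basis construction

The fitting basis is built from cubic B-splines with the two
second-derivative boundary constraints projected out via a QR null space
(the construction used by R's `ns`), giving `K + 1` columns for `K`
interior knots and good conditioning. Outside the boundary knots every
column is continued linearly from its boundary value and slope — the
defining "natural" behaviour, and the reason severely reduced patient FEV1
values (down to ~0.6 L, far below healthy boundary knots) receive linear,
never cubic, extrapolation. Predictions are never clamped to the training
age range; covariates outside the training ranges trigger a warning, not
an error. An independent truncated-power construction of the same function
space (`N₁ = x`, `N_{k+1} = d_k − d_{K+1}` with
`d_k(x) = [(x − t_k)₊³ − (x − t_m)₊³]/(t_m − t_k)`) is kept solely as a
test oracle: OLS fitted values on the two bases agree to ~1e−13, and this
dual route is asserted in the suite rather than collapsing both onto one
implementation.

## Normal limits of Δ lung age

Δ lung age of healthy subjects declines with chronological age, so the
upper limit of normal is derived from an OLS regression of Δ on age with
both sexes pooled (healthy males and females show no material Δ
difference, and one pooled formula is the convention):
`ULN(age) = intercept + slope·age + z·RSE` with `z = 1.645` (one-sided
95%), configurable. Negative ULN values at high ages are reported as-is —
the published coefficients go negative above age ≈ 73.7 and suppressing
that would change the rule. A symmetric lower limit (`fit − z·RSE`) is
implemented but off by default, since only the upper limit is of clinical
interest here. The constant alternative is the 95th percentile of healthy
Δ (linear interpolation between order statistics).

Classification: `consistent` (Δ ≤ 0), `older_within_uln` (0 < Δ ≤ ULN),
`above_uln` (Δ > ULN); a Δ exactly at the limit counts as within. Stages
on FEV1%pred use half-open bands I [80, ∞), II [50, 80), III [30, 50),
IV (0, 30). Published sources disagree on whether stage IV is `< 30` or
`> 30`; the convention adopted here (`< 30`) follows the GOLD severity
ordering and the fact that reported stage-IV cohort means (~24%) only make
sense below 30.

## Cohort construction

The healthy-reference inclusion filter applies, in order: age in [18, 80],
BMI ≤ 30 kg/m², never-smoker, and FEV1/FVC/FEV1:FVC/MMEF "within normal
limits". The normal-limit judgement depends on external reference
equations, so it is consumed as precomputed boolean flag columns and never
computed internally. Each exclusion is logged with the first failed rule.

Propensity matching balances age, height and sex between patients and
healthy subjects: a logistic model of group membership, greedy
nearest-neighbour matching on the logit without replacement, cases visited
in seeded random order, caliper 0.2 × SD of the logit. All of ratio,
caliper and covariates are configurable; these specifics are the standard
defaults of the matching literature, adopted because only the method
itself, not its settings, is prescribed. Complete separation raises an
explicit error suggesting exact matching. Balance is reported as
standardized mean differences (pooled-SD denominator; pooled binomial SD
for sex).

## Synthetic cohort generator

Twelve built-in profiles carry the target means/SDs of the reference
cohort tables: `healthy_modelling` (n = 2931), `healthy_validation`
(n = 478), `copd_stage_I..IV` (n = 70 each), `asthma_stage_I..IV`
(n = 78/78/78/52) and the two matched-healthy columns. Targets cover age,
height, weight, FEV1, FVC, MMEF, FEF50, FEF75 and FEV1%pred; sex splits
use the printed male/female counts.

**Healthy cohorts.** Age is a truncated normal on [18, 80] whose parent
parameters are solved so the truncated moments match the targets. Height
is normal per sex with a fixed 8 cm male–female gap and the within-sex SD
solved from the pooled moments (the tables print pooled values only; the
per-sex split is an internal modelling choice). Weight is correlated 0.45
with height and capped below BMI 29.9 so generated healthy cohorts pass
the inclusion filter by construction. Each spirometric quantity follows a
deterministic score — **quadratic in age peaking at 25 y** (scale 30 y),
plus height and sex terms — plus Gaussian noise loaded on a shared latent
"lung size" factor; FVC noise is additionally coupled to FEV1 noise
(ρ = 0.92) so FEV1 ≤ FVC holds essentially surely. The quadratic peak-
then-decline is the minimal realistic shape of adult lung-function
trajectories and is what makes the spline family measurably outperform a
straight line in FEV1. Flows (MMEF, FEF50, FEF75) are generated on an
exponential scale (short left tail) so positivity needs no distorting
floor. FEV1%pred is an affine map of the FEV1 noise component, so low
%pred coincides with FEV1 below the age/height/sex expectation.

After generation every calibrated quantity is affinely mapped so the
*sample* mean and SD equal the profile targets exactly; consistency clips
(FEV1 ≤ FVC, FEF50 ≥ FEF75, positive flows, BMI cap, age range) follow and
move the realised moments by far less than one Monte-Carlo standard error.
FEV1/FVC is derived, not calibrated; its mean lands near the printed value
automatically.

**Patient cohorts.** FEV1%pred is drawn from a normal truncated to the
stage band, with parent parameters solved so the truncated moments match
the printed stage mean/SD — band membership is guaranteed by construction.
Volumes and flows are moment-matched lognormals sharing a latent severity
factor (log-space loading 0.6; FVC again coupled to FEV1 at 0.92). A
lognormal is used because several printed patient SDs exceed their means
(e.g. severe-asthma MMEF 0.39 ± 0.63 L/s, CV ≈ 1.6), which no positive
truncated normal can attain, while a lognormal matches any such pair
exactly and stays positive. For the same reason FEF50 ≥ FEF75 is *not*
hard-enforced for patients: the printed severe-stage marginals overlap so
heavily that enforcement would visibly distort the calibrated moments;
ordering is only encouraged via the shared factor. (For healthy cohorts,
where crossings are <2%, the ordering clip is applied.) Stage-profile
metadata also exposes the implied flow-depression ratios relative to the
healthy modelling profile.

What the generator does **not** emulate: between-parameter correlation
targets (not printed anywhere), longitudinal decline, smoking exposure,
per-sex spirometry tables (only pooled targets are printed), or a real
%pred reference equation (patient %pred and absolute FEV1 are each
calibrated to their own printed moments and are therefore not linked by
one fixed reference equation). Passing tests show the pipeline behaves
correctly under these study-shaped conditions, not that it reproduces any
real cohort's subject-level structure.

## Problem sizes and numerical choices

- Reproducibility: every stochastic routine takes a seed
  (`numpy.random.default_rng`); same seed → byte-identical cohorts and
  artifacts.
- The spline-vs-MLR comparison uses 100 replicates of 1500 training / 800
  held-out records — large enough that the held-out Δ-MSE ordering is
  stable, small enough to run in seconds.
- ULN parameter recovery uses n = 1e5 null draws; coverage uses n = 3000.
- Truncated-normal moment matching solves the two-moment system with
  Levenberg–Marquardt starting from the untruncated parameters; near-flat
  cases (stage bands almost uniform) converge to the closest attainable
  pair, and the subsequent sample standardization absorbs any residual
  gap.
- Quantiles everywhere (knots, constant ULN, breakpoint grids) use linear
  interpolation between order statistics.
- Degenerate inputs fail loudly: constant predictors name the collinear
  column, constant ages make the ULN slope unidentifiable, empty strata
  and empty Δ samples raise, corrupted model files never yield partial
  models.
- Serialized predictions are bit-reproducible: equations sum their linear
  terms in sorted order, and model JSON stores coefficients at full
  precision with sorted keys.

## Known limitations

- The published spline equations cannot be evaluated without the
  separately distributed `ns(FEV1)` knots and coefficients; the loader
  refuses to predict from the linear part alone rather than silently
  returning wrong lung ages.
- Backward regression compresses: predicted lung age has smaller variance
  than chronological age, so Δ is negatively correlated with age even in
  healthy data — this is intrinsic to the approach and is exactly why the
  age-dependent ULN exists.
- The quadratic age curve makes the age–FEV1 relation non-monotone below
  its peak; backward prediction is ambiguous there for every model family.
- Synthetic fit statistics (adjusted R² ≈ 0.6, RSE ≈ 9.5 y at reference
  sizes) are in the neighbourhood of, but not identical to, reference
  values: they depend on the generator's noise structure, which is an
  emulation, not the real cohort.
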