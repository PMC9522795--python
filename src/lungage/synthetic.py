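"""Synthetic spirometry cohorts with the structure the pipeline assumes.

Generates healthy and staged COPD/asthma cohorts whose demographic and
spirometric summary statistics reproduce the reference cohort tables the
package's built-in profiles are calibrated to, so the whole modelling
pipeline is testable with no external data.

Design of the healthy generator
-------------------------------
* Age is a moment-matched truncated normal on [18, 80]; height is normal
  per sex (an 8 cm male–female gap, within-sex SD solved so the pooled
  moments match); weight is correlated with height and kept below the
  BMI 30 kg/m² inclusion ceiling by construction.
* Each spirometric quantity (FEV1, FVC, MMEF, FEF50, FEF75) follows a
  deterministic mean function — **quadratic in age with a peak in the
  mid-20s** (lung function rises to a plateau then declines, and the
  nonlinearity is what makes spline regression outperform a straight
  line) — plus height and sex effects and Gaussian noise sharing a
  per-subject latent "lung size" factor so the quantities are mutually
  correlated.
* Every calibrated quantity is then affinely standardized so the *sample*
  mean and SD equal the profile targets exactly, followed by consistency
  clips (FEV1 ≤ FVC, positive flows, FEF50 ≥ FEF75, BMI ceiling).  The
  clips move the realised moments by far less than one Monte-Carlo
  standard error.

Design of the patient generator
-------------------------------
FEV1%pred is drawn from a moment-matched normal truncated to the stage's
airflow-limitation band, guaranteeing band membership.  Volumes and flows
are moment-matched lognormals sharing a latent severity factor: several
printed patient SDs exceed their means (CV > 1), which no positive
truncated normal can attain, while a lognormal matches any such pair
exactly and stays positive.

Same seed → byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from types import MappingProxyType

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .norms import stage_band

__all__ = [
    "GeneratorProfile",
    "builtin_profiles",
    "get_profile",
    "generate_healthy",
    "generate_patients",
    "generate_cohort",
    "generate_delta_null",
]

SPIRO_QUANTITIES = ("fev1", "fvc", "mmef", "fef50", "fef75")
CALIBRATED_QUANTITIES = (
    "age", "height", "weight", *SPIRO_QUANTITIES, "fev1_pct_pred",
)

_SEX_HEIGHT_GAP_CM = 8.0
_HEIGHT_WEIGHT_CORR = 0.45
_AGE_PEAK = 25.0  # years; lung function plateaus in the mid-20s
_AGE_SCALE = 30.0

# Relative structure of the healthy spirometry model: weights of the age
# curve, height, sex and noise components (absolute scale is irrelevant —
# each quantity is standardized to its profile targets), plus the loading
# of the noise on the shared latent factor.
_HEALTHY_STRUCTURE = {
    "fev1": {"age": 1.00, "height": 0.35, "sex": 0.30, "noise": 0.50, "rho": 0.75},
    "fvc": {"age": 0.80, "height": 0.40, "sex": 0.35, "noise": 0.55, "rho": 0.80},
    "mmef": {"age": 1.00, "height": 0.10, "sex": 0.10, "noise": 0.80, "rho": 0.40},
    "fef50": {"age": 1.00, "height": 0.12, "sex": 0.12, "noise": 0.75, "rho": 0.40},
    "fef75": {"age": 1.15, "height": 0.08, "sex": 0.08, "noise": 0.65, "rho": 0.40},
}
#: flows are generated on an exponential scale (short left tail keeps them
#: positive without clipping); volumes stay additive
_MULTIPLICATIVE = ("mmef", "fef50", "fef75")
_PATIENT_LOG_RHO = 0.6  # latent severity loading in log space
_FEV1_FVC_PAIR_RHO = 0.92  # extra FEV1–FVC coupling so FEV1 <= FVC almost surely


@dataclass(frozen=True)
class GeneratorProfile:
    """Calibration of the synthetic cohort generator for one cohort column."""

    label: str
    group: str  # 'healthy' | 'copd' | 'asthma'
    stage: str | None
    n_reference: int
    n_male: int
    n_female: int
    age_mean: float
    age_sd: float
    height_mean: float
    height_sd: float
    weight_mean: float
    weight_sd: float
    spiro: dict  # quantity -> (mean, sd); includes 'fev1_pct_pred'
    age_range: tuple[float, float] = (18.0, 80.0)

    def __post_init__(self) -> None:
        for q, (m, s) in self.spiro.items():
            if s < 0:
                raise ValueError(f"{self.label}: negative SD for {q}")
        object.__setattr__(self, "spiro", MappingProxyType(dict(self.spiro)))

    @property
    def male_fraction(self) -> float:
        return self.n_male / (self.n_male + self.n_female)

    @property
    def pct_pred_band(self) -> tuple[float, float] | None:
        """Stage FEV1%pred band; consistent with the staging rule."""
        if self.stage is None:
            return None
        return stage_band(self.stage)

    def flow_depression(self, reference: "GeneratorProfile | str" = "healthy_modelling") -> dict[str, float]:
        """Ratio of this profile's mean flows/volumes to a healthy reference
        profile's — the severity multipliers implied by the stage targets."""
        ref = get_profile(reference)
        return {
            q: self.spiro[q][0] / ref.spiro[q][0]
            for q in SPIRO_QUANTITIES
        }

    def target(self, quantity: str) -> tuple[float, float]:
        if quantity == "age":
            return (self.age_mean, self.age_sd)
        if quantity == "height":
            return (self.height_mean, self.height_sd)
        if quantity == "weight":
            return (self.weight_mean, self.weight_sd)
        return tuple(self.spiro[quantity])


def _profile(label, group, stage, n, males, females, age, height, weight,
             fev1, pct, fvc, mmef, fef50, fef75) -> GeneratorProfile:
    return GeneratorProfile(
        label=label, group=group, stage=stage, n_reference=n,
        n_male=males, n_female=females,
        age_mean=age[0], age_sd=age[1],
        height_mean=height[0], height_sd=height[1],
        weight_mean=weight[0], weight_sd=weight[1],
        spiro={
            "fev1": fev1, "fev1_pct_pred": pct, "fvc": fvc,
            "mmef": mmef, "fef50": fef50, "fef75": fef75,
        },
    )


_PROFILES = {
    p.label: p
    for p in [
        _profile("healthy_modelling", "healthy", None, 2931, 1379, 1552,
                 (37.85, 14.92), (170.21, 6.06), (67.65, 9.60),
                 (3.81, 0.63), (101.94, 9.64), (4.54, 0.69),
                 (4.02, 1.13), (4.83, 1.27), (1.91, 0.79)),
        _profile("healthy_validation", "healthy", None, 478, 192, 286,
                 (42.41, 15.67), (162.53, 8.32), (62.30, 10.80),
                 (3.11, 0.75), (103.52, 9.53), (3.75, 0.88),
                 (3.17, 1.06), (4.01, 1.17), (1.39, 0.70)),
        _profile("copd_matched_healthy", "healthy", None, 70, 58, 12,
                 (62.16, 7.72), (162.48, 6.66), (63.78, 9.57),
                 (2.83, 0.57), (101.25, 11.00), (3.57, 0.67),
                 (2.66, 0.94), (3.76, 1.17), (1.17, 0.51)),
        _profile("asthma_matched_healthy", "healthy", None, 78, 39, 43,
                 (50.79, 14.42), (160.10, 8.39), (61.89, 9.57),
                 (2.93, 0.80), (101.73, 10.44), (3.61, 0.93),
                 (2.89, 1.02), (3.84, 1.15), (1.11, 0.58)),
        _profile("copd_stage_I", "copd", "I", 70, 59, 11,
                 (61.85, 7.07), (164.12, 6.96), (63.28, 10.46),
                 (2.46, 0.37), (87.84, 5.64), (3.87, 0.57),
                 (1.18, 0.25), (1.62, 0.52), (0.39, 0.16)),
        _profile("copd_stage_II", "copd", "II", 70, 57, 13,
                 (62.26, 6.95), (164.28, 7.27), (60.65, 11.17),
                 (1.81, 0.34), (65.00, 8.45), (3.14, 0.54),
                 (0.75, 0.26), (1.02, 0.39), (0.30, 0.10)),
        _profile("copd_stage_III", "copd", "III", 70, 58, 12,
                 (62.43, 7.40), (164.32, 6.90), (59.16, 10.54),
                 (1.12, 0.25), (39.99, 6.31), (2.58, 0.66),
                 (0.40, 0.11), (0.48, 0.15), (0.20, 0.06)),
        _profile("copd_stage_IV", "copd", "IV", 70, 58, 12,
                 (63.79, 6.93), (163.06, 8.45), (54.71, 10.29),
                 (0.66, 0.15), (24.26, 3.89), (1.94, 0.46),
                 (0.24, 0.06), (0.26, 0.09), (0.14, 0.05)),
        _profile("asthma_stage_I", "asthma", "I", 78, 39, 43,
                 (50.87, 12.51), (161.56, 7.51), (63.69, 12.44),
                 (2.73, 0.67), (92.39, 8.23), (3.68, 0.89),
                 (2.03, 0.89), (2.69, 1.05), (0.77, 0.45)),
        _profile("asthma_stage_II", "asthma", "II", 78, 42, 40,
                 (50.23, 13.22), (162.89, 8.29), (64.67, 11.41),
                 (1.94, 0.47), (62.94, 7.92), (3.27, 0.84),
                 (1.07, 0.58), (1.28, 0.55), (0.37, 0.19)),
        _profile("asthma_stage_III", "asthma", "III", 78, 44, 38,
                 (49.30, 15.08), (161.19, 9.34), (61.37, 11.31),
                 (1.20, 0.35), (40.43, 5.86), (2.57, 0.86),
                 (0.46, 0.39), (0.54, 0.20), (0.19, 0.09)),
        _profile("asthma_stage_IV", "asthma", "IV", 52, 28, 15,
                 (55.01, 13.13), (160.30, 7.92), (57.61, 11.27),
                 (0.65, 0.17), (23.52, 4.72), (1.84, 0.49),
                 (0.39, 0.63), (0.34, 0.57), (0.15, 0.21)),
    ]
}


def builtin_profiles() -> dict[str, GeneratorProfile]:
    """All built-in cohort profiles, keyed by label."""
    return dict(_PROFILES)


def get_profile(name) -> GeneratorProfile:
    if isinstance(name, GeneratorProfile):
        return name
    try:
        return _PROFILES[name]
    except KeyError:
        raise ValueError(
            f"unknown profile {name!r}; available: {', '.join(sorted(_PROFILES))}"
        ) from None


# -- numeric helpers ------------------------------------------------------
@lru_cache(maxsize=None)
def _truncnorm_params(mean: float, sd: float, lo: float, hi: float):
    """Parent (mu, sigma) of a truncated normal whose truncated moments on
    [lo, hi] match (mean, sd) as closely as attainable."""

    def residuals(x):
        mu, log_sigma = x
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(m) - mean, float(np.sqrt(v)) - sd]

    sol = optimize.least_squares(
        residuals, x0=[mean, np.log(sd)], method="lm", xtol=1e-12, ftol=1e-12
    )
    mu, sigma = sol.x[0], float(np.exp(sol.x[1]))
    return mu, sigma


def _truncnorm_sample(rng, n, mean, sd, lo, hi):
    mu, sigma = _truncnorm_params(mean, sd, lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n, random_state=rng)


def _standardize_to(values: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Affinely map a sample so its mean and (ddof=1) SD equal the targets."""
    values = np.asarray(values, dtype=float)
    if values.size < 2 or sd == 0:
        return values - values.mean() + mean
    s = values.std(ddof=1)
    if s == 0:
        return np.full_like(values, mean)
    return mean + sd * (values - values.mean()) / s


def _sex_heights(profile: GeneratorProfile):
    """Per-sex height means and within-sex SD matching the pooled moments."""
    mf = profile.male_fraction
    gap = _SEX_HEIGHT_GAP_CM
    pooled_var = profile.height_sd**2
    between = mf * (1 - mf) * gap**2
    if between >= pooled_var:
        gap = np.sqrt(0.5 * pooled_var / max(mf * (1 - mf), 1e-9))
        between = mf * (1 - mf) * gap**2
    within_sd = np.sqrt(pooled_var - between)
    female_mean = profile.height_mean - mf * gap
    return female_mean + gap, female_mean, within_sd


def _demographics(rng, profile: GeneratorProfile, n: int):
    n_male = int(round(n * profile.male_fraction))
    sex = np.array(["male"] * n_male + ["female"] * (n - n_male))
    male = (sex == "male").astype(float)

    lo, hi = profile.age_range
    age = _truncnorm_sample(rng, n, profile.age_mean, profile.age_sd, lo, hi)
    age = np.clip(_standardize_to(age, profile.age_mean, profile.age_sd), lo, hi)

    m_mean, f_mean, within_sd = _sex_heights(profile)
    height = np.where(male == 1, m_mean, f_mean) + within_sd * rng.standard_normal(n)
    height = np.clip(
        _standardize_to(height, profile.height_mean, profile.height_sd), 121.0, 209.0
    )
    zh = (height - profile.height_mean) / max(profile.height_sd, 1e-9)

    w_raw = _HEIGHT_WEIGHT_CORR * zh + np.sqrt(1 - _HEIGHT_WEIGHT_CORR**2) * rng.standard_normal(n)
    weight = _standardize_to(w_raw, profile.weight_mean, profile.weight_sd)
    return sex, male, age, height, zh, weight


def _age_curve(age: np.ndarray) -> np.ndarray:
    return -(((age - _AGE_PEAK) / _AGE_SCALE) ** 2)


def generate_healthy(profile="healthy_modelling", n: int | None = None, seed=None) -> pd.DataFrame:
    """Generate a healthy spirometry cohort calibrated to a profile.

    ``n`` defaults to the profile's reference cohort size.  Records satisfy
    18 ≤ age ≤ 80, FEV1 ≤ FVC, positive flows and BMI ≤ 30, carry
    ``*_normal`` flags set True and ``smoker`` False, and pass the healthy
    inclusion filter by construction.
    """
    profile = get_profile(profile)
    if profile.group != "healthy":
        raise ValueError(f"profile {profile.label!r} is not a healthy profile")
    if n is None:
        n = profile.n_reference
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    sex, male, age, height, zh, weight = _demographics(rng, profile, n)

    shape = _age_curve(age)
    latent = rng.standard_normal(n)
    values: dict[str, np.ndarray] = {}
    fev1_noise = None
    for q in SPIRO_QUANTITIES:
        w = _HEALTHY_STRUCTURE[q]
        eps = rng.standard_normal(n)
        if q == "fvc":
            # couple FVC noise tightly to FEV1 so FEV1 <= FVC almost surely
            noise = (
                _FEV1_FVC_PAIR_RHO * fev1_noise
                + np.sqrt(1 - _FEV1_FVC_PAIR_RHO**2) * eps
            )
        else:
            noise = w["rho"] * latent + np.sqrt(1 - w["rho"] ** 2) * eps
        if q == "fev1":
            fev1_noise = noise
        score = w["age"] * shape + w["height"] * zh + w["sex"] * male + w["noise"] * noise
        mean, sd = profile.spiro[q]
        if q in _MULTIPLICATIVE and n > 1 and score.std() > 0:
            sigma_log = np.sqrt(np.log1p((sd / mean) ** 2))
            score = np.exp(sigma_log * (score - score.mean()) / score.std())
        values[q] = _standardize_to(score, mean, sd)

    # consistency clips — shifts are far below one standard error
    values["fev1"] = np.maximum(values["fev1"], 0.05)
    values["fvc"] = np.maximum(values["fvc"], values["fev1"] / 0.995)
    for q in _MULTIPLICATIVE:
        values[q] = np.maximum(values[q], 0.01)
    values["fef50"] = np.maximum(values["fef50"], 1.02 * values["fef75"])

    pct_mean, pct_sd = profile.spiro["fev1_pct_pred"]
    pct = np.maximum(_standardize_to(fev1_noise, pct_mean, pct_sd), 20.0)

    # keep BMI below the inclusion ceiling by construction; one
    # re-standardization pass compensates most of the clipping shift
    bmi_cap = 29.9 * (height / 100.0) ** 2
    weight = np.clip(weight, 35.0, bmi_cap)
    weight = _standardize_to(weight, profile.weight_mean, profile.weight_sd)
    weight = np.clip(weight, 35.0, bmi_cap)

    return _assemble(profile, seed, sex, age, height, weight, values, pct,
                     flags=True, smoker=False)


def generate_patients(
    disease: str | None = None,
    stage: str | None = None,
    n: int | None = None,
    seed=None,
    profile=None,
) -> pd.DataFrame:
    """Generate a staged COPD or asthma cohort.

    Either pass ``disease`` ('copd' or 'asthma') and ``stage`` ('I'–'IV'),
    or a patient `GeneratorProfile`.  Every record's FEV1%pred lies inside
    the stage band; flows and volumes are depressed relative to healthy in
    proportion to the profile's stage targets.
    """
    if profile is None:
        if disease is None or stage is None:
            raise ValueError("pass disease and stage, or a patient profile")
        profile = get_profile(f"{disease}_stage_{stage}")
    else:
        profile = get_profile(profile)
    if profile.group not in ("copd", "asthma"):
        raise ValueError(f"profile {profile.label!r} is not a patient profile")
    if n is None:
        n = profile.n_reference
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    sex, male, age, height, zh, weight = _demographics(rng, profile, n)
    weight = np.maximum(weight, 30.0)

    band_lo, band_hi = profile.pct_pred_band
    lo = max(band_lo, 1.0)
    hi = band_hi if np.isfinite(band_hi) else profile.spiro["fev1_pct_pred"][0] + 8 * profile.spiro["fev1_pct_pred"][1]
    pct_mean, pct_sd = profile.spiro["fev1_pct_pred"]
    pct = _truncnorm_sample(rng, n, pct_mean, pct_sd, lo, hi)
    pct = np.clip(_standardize_to(pct, pct_mean, pct_sd), lo + 1e-9, hi - 1e-9)

    latent = rng.standard_normal(n)
    values: dict[str, np.ndarray] = {}
    z_fev1 = None
    for q in SPIRO_QUANTITIES:
        mean, sd = profile.spiro[q]
        cv2 = (sd / mean) ** 2
        sigma_log = np.sqrt(np.log1p(cv2))
        mu_log = np.log(mean) - 0.5 * sigma_log**2
        eps = rng.standard_normal(n)
        if q == "fvc":
            z = (
                _FEV1_FVC_PAIR_RHO * z_fev1
                + np.sqrt(1 - _FEV1_FVC_PAIR_RHO**2) * eps
            )
        else:
            z = _PATIENT_LOG_RHO * latent + np.sqrt(1 - _PATIENT_LOG_RHO**2) * eps
        if q == "fev1":
            z_fev1 = z
        raw = np.exp(mu_log + sigma_log * z)
        values[q] = np.maximum(_standardize_to(raw, mean, sd), 0.01)

    values["fvc"] = np.maximum(values["fvc"], values["fev1"] / 0.995)

    return _assemble(profile, seed, sex, age, height, weight, values, pct,
                     flags=False, smoker=(profile.group == "copd"))


def generate_cohort(profile, n: int | None = None, seed=None) -> pd.DataFrame:
    """Generate a cohort from any built-in profile (healthy or patient)."""
    profile = get_profile(profile)
    if profile.group == "healthy":
        return generate_healthy(profile, n=n, seed=seed)
    return generate_patients(profile=profile, n=n, seed=seed)


def _assemble(profile, seed, sex, age, height, weight, values, pct,
              flags: bool, smoker: bool) -> pd.DataFrame:
    n = len(sex)
    fev1 = values["fev1"]
    fvc = values["fvc"]
    df = pd.DataFrame(
        {
            "id": [f"{profile.label}_{i + 1:05d}" for i in range(n)],
            "sex": sex,
            "age": age,
            "height": height,
            "weight": weight,
            "fev1": fev1,
            "fvc": fvc,
            "fev1_fvc": fev1 / fvc,
            "fev1_pct_pred": pct,
            "mmef": values["mmef"],
            "fef50": values["fef50"],
            "fef75": values["fef75"],
            "fev1_normal": flags if flags else pct >= 80.0,
            "fvc_normal": flags,
            "fev1_fvc_normal": flags,
            "mmef_normal": flags,
            "smoker": smoker,
        }
    )
    df.attrs["profile"] = profile.label
    df.attrs["seed"] = seed
    return df


def generate_delta_null(
    coefficients=(12.243, -0.323, 7.037),
    age_distribution=(37.85, 14.92),
    age_range=(18.0, 80.0),
    n: int = 1000,
    seed=None,
):
    """Draw (ages, deltas) from the Δ-on-age regression truth.

    ``coefficients`` is (intercept, age slope, residual SD); deltas are
    ``intercept + slope·age + N(0, rse²)``.  Used for ULN
    parameter-recovery and coverage checks.
    """
    if n < 10:
        raise ValueError(f"n must be >= 10, got {n}")
    intercept, slope, rse = coefficients
    if rse < 0:
        raise ValueError("residual SD must be >= 0")
    rng = np.random.default_rng(seed)
    mean, sd = age_distribution
    ages = _truncnorm_sample(rng, n, mean, sd, *age_range)
    deltas = intercept + slope * ages + rse * rng.standard_normal(n)
    return ages, deltas
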