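"""Normal limits of Δ lung age, classification, and airflow-limitation stages.

Because Δ lung age of healthy subjects declines with chronological age, the
upper limit of normal (ULN) is age-dependent: an OLS regression of Δ on age
gives ``ULN(age) = intercept + slope·age + z·RSE`` with ``z = 1.645``
(one-sided 95%).  The published coefficients are
``12.243 − 0.323·age + 1.645 × 7.037`` (spline equations) and
``14.690 − 0.392·age + 1.645 × 7.387`` (MLR equations); negative ULN values
at high ages are legal output and are reported as-is.  A constant ULN is the
95th percentile of healthy Δ values.

Stages I–IV follow the GOLD airflow-limitation bands on FEV1%pred:
I ≥ 80, 50 ≤ II < 80, 30 ≤ III < 50, IV < 30.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "UlnModel",
    "Stage",
    "STAGES",
    "PUBLISHED_ULN_SPLINE",
    "PUBLISHED_ULN_MLR",
    "derive_age_dependent_uln",
    "uln_at_age",
    "derive_constant_uln",
    "classify_delta",
    "gold_stage",
    "exceedance_table",
]

LABEL_CONSISTENT = "consistent"
LABEL_OLDER_WITHIN = "older_within_uln"
LABEL_ABOVE = "above_uln"


@dataclass(frozen=True)
class UlnModel:
    """Δ-lung-age normal-limit model.

    ``uln_at_age(a) = intercept + age_slope·a + z·rse``; the optional
    ``constant_uln`` is a percentile-based age-independent limit.
    """

    intercept: float
    age_slope: float
    rse: float
    z: float = 1.645
    constant_uln: float | None = None
    source_label: str = "derived"

    def __post_init__(self) -> None:
        if self.rse < 0:
            raise ValueError(f"rse must be >= 0, got {self.rse}")
        if self.z <= 0:
            raise ValueError(f"z must be > 0, got {self.z}")

    def uln_at_age(self, age):
        age = np.asarray(age, dtype=float)
        out = self.intercept + self.age_slope * age + self.z * self.rse
        return float(out) if out.ndim == 0 else out

    def lln_at_age(self, age):
        """Symmetric lower limit (fit − z·RSE); provided for completeness."""
        age = np.asarray(age, dtype=float)
        out = self.intercept + self.age_slope * age - self.z * self.rse
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "age_slope": self.age_slope,
            "rse": self.rse,
            "z": self.z,
            "constant_uln": self.constant_uln,
            "source_label": self.source_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UlnModel":
        return cls(
            intercept=float(d["intercept"]),
            age_slope=float(d["age_slope"]),
            rse=float(d["rse"]),
            z=float(d.get("z", 1.645)),
            constant_uln=(None if d.get("constant_uln") is None else float(d["constant_uln"])),
            source_label=d.get("source_label", "derived"),
        )


#: ULN of Δ lung age derived from the spline lung-age equations.
PUBLISHED_ULN_SPLINE = UlnModel(12.243, -0.323, 7.037, source_label="published_spline")
#: ULN of Δ lung age derived from the multiple-linear-regression equations.
PUBLISHED_ULN_MLR = UlnModel(14.690, -0.392, 7.387, source_label="published_mlr")


def derive_age_dependent_uln(deltas, ages, z: float = 1.645, constant_percentile=None) -> UlnModel:
    """Regress Δ lung age on chronological age and add ``z·RSE``.

    Sexes are pooled (healthy males and females show no difference in Δ).
    ``constant_percentile`` additionally stores the percentile-based constant
    limit on the returned model.
    """
    deltas = np.asarray(deltas, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if deltas.shape != ages.shape:
        raise ValueError("deltas and ages must be paired (same length)")
    n = deltas.size
    if n < 10:
        raise ValueError(f"need at least 10 paired observations, got {n}")
    if np.ptp(ages) == 0:
        raise ValueError("ages are constant; the age slope is unidentifiable")
    X = np.column_stack([np.ones(n), ages])
    beta, _, _, _ = np.linalg.lstsq(X, deltas, rcond=None)
    resid = deltas - X @ beta
    rse = float(np.sqrt(resid @ resid / (n - 2)))
    constant = None
    if constant_percentile is not None:
        constant = derive_constant_uln(deltas, constant_percentile)
    return UlnModel(
        intercept=float(beta[0]),
        age_slope=float(beta[1]),
        rse=rse,
        z=z,
        constant_uln=constant,
    )


def uln_at_age(uln: UlnModel, age):
    """Functional alias for :meth:`UlnModel.uln_at_age`."""
    return uln.uln_at_age(age)


def derive_constant_uln(deltas, percentile: float = 0.95) -> float:
    """Age-independent ULN: the requested percentile of healthy Δ values,
    by linear interpolation between order statistics."""
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size == 0:
        raise ValueError("cannot derive a percentile from an empty sample")
    if not 0 < percentile < 1:
        raise ValueError(f"percentile must be in (0, 1), got {percentile}")
    return float(np.quantile(deltas, percentile))


def classify_delta(delta, age, uln: UlnModel, mode: str = "age_dependent"):
    """Three-way interpretation of Δ lung age against the ULN.

    ``consistent`` (Δ ≤ 0), ``older_within_uln`` (0 < Δ ≤ ULN) or
    ``above_uln`` (Δ > ULN); a Δ exactly at the ULN counts as within.
    """
    if mode == "age_dependent":
        limit = np.asarray(uln.uln_at_age(age), dtype=float)
    elif mode == "constant":
        if uln.constant_uln is None:
            raise ValueError("constant mode requires constant_uln on the UlnModel")
        limit = np.asarray(uln.constant_uln, dtype=float)
    else:
        raise ValueError(f"mode must be 'age_dependent' or 'constant', got {mode!r}")
    delta_arr = np.asarray(delta, dtype=float)
    limit_arr = np.broadcast_to(limit, delta_arr.shape)
    labels = np.where(
        delta_arr <= 0,
        LABEL_CONSISTENT,
        np.where(delta_arr <= limit_arr, LABEL_OLDER_WITHIN, LABEL_ABOVE),
    )
    return labels.item() if np.ndim(delta) == 0 else labels


@dataclass(frozen=True)
class Stage:
    """GOLD-style airflow-limitation severity band on FEV1%pred."""

    label: str
    band: tuple[float, float]  # [low, high) in %pred; high may be inf


STAGES = (
    Stage("I", (80.0, float("inf"))),
    Stage("II", (50.0, 80.0)),
    Stage("III", (30.0, 50.0)),
    Stage("IV", (0.0, 30.0)),
)
_STAGE_BY_LABEL = {s.label: s for s in STAGES}


def stage_band(label: str) -> tuple[float, float]:
    return _STAGE_BY_LABEL[label].band


def gold_stage(fev1_pct_pred):
    """Assign stage I–IV from FEV1%pred (half-open bands, stage IV < 30)."""
    arr = np.asarray(fev1_pct_pred, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("FEV1%pred must be positive and finite")
    labels = np.select(
        [arr >= 80.0, arr >= 50.0, arr >= 30.0],
        ["I", "II", "III"],
        default="IV",
    )
    return labels.item() if np.ndim(fev1_pct_pred) == 0 else labels


def exceedance_table(cohorts: dict[str, pd.DataFrame], uln_variants) -> pd.DataFrame:
    """Count Δ-lung-age exceedances per cohort × ULN variant.

    ``cohorts`` maps a cohort label to a frame with ``delta`` and ``age``
    columns; ``uln_variants`` is an iterable of ``(name, UlnModel, mode)``.
    Returns a tidy frame with over-ULN counts, totals and percentages
    (1 decimal), one row per cohort × variant.
    """
    rows = []
    for cohort, df in cohorts.items():
        if len(df) == 0:
            warnings.warn(f"cohort {cohort!r} is empty", UserWarning, stacklevel=2)
            for name, _, _ in uln_variants:
                rows.append(
                    {"cohort": cohort, "uln_variant": name, "n_over": 0,
                     "n_total": 0, "pct_over": float("nan")}
                )
            continue
        missing = {"delta", "age"} - set(df.columns)
        if missing:
            raise ValueError(f"cohort {cohort!r} lacks column(s): {sorted(missing)}")
        for name, uln, mode in uln_variants:
            labels = classify_delta(
                df["delta"].to_numpy(dtype=float), df["age"].to_numpy(dtype=float),
                uln, mode=mode,
            )
            n_over = int((labels == LABEL_ABOVE).sum())
            rows.append(
                {
                    "cohort": cohort,
                    "uln_variant": name,
                    "n_over": n_over,
                    "n_total": len(df),
                    "pct_over": round(100.0 * n_over / len(df), 1),
                }
            )
    return pd.DataFrame(rows)
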