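"""Lung-age equations: evaluation, Δ lung age, and the published coefficients.

A *lung-age equation* predicts the chronological age at which a healthy
nonsmoker would, on average, show the subject's spirometry ("backward"
prediction: age is the response).  Δ lung age = lung age − chronological
age; positive values mean lung function worse than the healthy average for
that age.

`LungAgeEquation` is the portable, serialisable form of a fitted model: an
intercept, linear coefficients (height in years/cm, flows in years per L/s),
and an FEV1 effect encoded exactly one of three ways — a linear
coefficient, a continuous one-breakpoint hinge, or natural-spline columns
with per-column coefficients.  Predictions are never clamped to the
training age range [18, 80]; out-of-range covariates trigger a warning, not
an error, because patient spirometry legitimately lies far below healthy
training values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .basis import KnotSet, natural_cubic_basis

__all__ = [
    "LungAgeEquation",
    "predict_lung_age",
    "delta_lung_age",
    "delta_mse",
    "compute_delta",
    "load_published_model",
    "PUBLISHED_LINEAR_COEFFICIENTS",
]

METHODS = ("mlr", "piecewise", "spline")

#: Linear part of the published sex-specific spline equations.  The natural
#: spline contribution of FEV1 was released separately (supplementary
#: material) and must be supplied by the user; see load_published_model.
PUBLISHED_LINEAR_COEFFICIENTS: dict[str, dict[str, float]] = {
    "male": {"intercept": 2.25, "height": 0.49, "fef50": 3.47, "fef75": -8.92},
    "female": {"intercept": 28.49, "height": 0.36, "fef50": 4.45, "fef75": -12.52},
}


class MissingPredictorError(KeyError):
    pass


@dataclass
class LungAgeEquation:
    """A fitted or published backward-age equation for one sex."""

    sex: str
    method: str
    intercept: float
    linear_terms: dict[str, float] = field(default_factory=dict)
    knots: KnotSet | None = None
    spline_coefficients: tuple[float, ...] | None = None
    breakpoint: float | None = None
    hinge_coefficient: float | None = None
    training_ranges: dict[str, tuple[float, float]] | None = None
    model_id: str = ""

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        encodings = [
            "fev1" in self.linear_terms and self.method == "mlr",
            self.spline_coefficients is not None,
            self.breakpoint is not None,
        ]
        if sum(encodings) != 1:
            raise ValueError(
                "exactly one of a linear FEV1 term, a spline spec, or a "
                "breakpoint spec must encode the FEV1 effect"
            )
        if self.spline_coefficients is not None:
            if self.knots is None:
                raise ValueError("spline coefficients supplied without knots")
            if len(self.spline_coefficients) != self.knots.n_columns:
                raise ValueError(
                    f"spline coefficient count {len(self.spline_coefficients)} "
                    f"does not match knot-implied column count {self.knots.n_columns}"
                )
        if self.breakpoint is not None and self.hinge_coefficient is None:
            raise ValueError("breakpoint supplied without a hinge coefficient")
        if not self.model_id:
            self.model_id = f"{self.method}_{self.sex}"

    @property
    def required_columns(self) -> list[str]:
        # every method encodes an FEV1 effect one way or another
        return ["fev1"] + [k for k in self.linear_terms if k != "fev1"]

    def fev1_contribution(self, fev1) -> np.ndarray:
        """Years contributed by the FEV1 term alone."""
        fev1 = np.asarray(fev1, dtype=float)
        if self.spline_coefficients is not None:
            basis = natural_cubic_basis(fev1.ravel(), self.knots)
            return (basis @ np.asarray(self.spline_coefficients)).reshape(fev1.shape)
        if self.breakpoint is not None:
            slope = self.linear_terms.get("fev1", 0.0)
            hinge = np.maximum(fev1 - self.breakpoint, 0.0)
            return slope * fev1 + self.hinge_coefficient * hinge
        return self.linear_terms["fev1"] * fev1

    def predict(self, records) -> np.ndarray:
        """Predicted lung age (years) for a record table or a single record."""
        scalar = isinstance(records, (Mapping, pd.Series))
        df = _as_frame(records)
        if "sex" in df.columns:
            other = df.loc[df["sex"] != self.sex]
            if len(other):
                raise ValueError(
                    f"model is sex-specific ({self.sex}); records include "
                    f"{len(other)} record(s) of the other sex"
                )
        missing = [c for c in self.required_columns if c not in df.columns]
        if missing:
            raise MissingPredictorError(
                f"missing predictor column(s): {', '.join(missing)}"
            )
        self._warn_out_of_range(df)
        out = np.full(len(df), self.intercept, dtype=float)
        # fixed (sorted) summation order so serialization round trips predict
        # bit-for-bit identically
        for name in sorted(self.linear_terms):
            if name == "fev1":
                continue
            out += self.linear_terms[name] * df[name].to_numpy(dtype=float)
        out += self.fev1_contribution(df["fev1"].to_numpy(dtype=float))
        return float(out[0]) if scalar else out

    def _warn_out_of_range(self, df: pd.DataFrame) -> None:
        if not self.training_ranges:
            return
        hit = []
        for name, (lo, hi) in self.training_ranges.items():
            if name in df.columns:
                v = df[name].to_numpy(dtype=float)
                n_out = int(((v < lo) | (v > hi)).sum())
                if n_out:
                    hit.append(f"{name} ({n_out} outside [{lo:.4g}, {hi:.4g}])")
        if hit:
            warnings.warn(
                "predictors outside the model's training ranges — predictions "
                "are linear extrapolations: " + "; ".join(hit),
                UserWarning,
                stacklevel=3,
            )

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "sex": self.sex,
            "method": self.method,
            "intercept": self.intercept,
            "linear_terms": dict(self.linear_terms),
            "knots": self.knots.to_dict() if self.knots else None,
            "spline_coefficients": (
                list(self.spline_coefficients)
                if self.spline_coefficients is not None
                else None
            ),
            "breakpoint": self.breakpoint,
            "hinge_coefficient": self.hinge_coefficient,
            "training_ranges": (
                {k: list(v) for k, v in self.training_ranges.items()}
                if self.training_ranges
                else None
            ),
            "model_id": self.model_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LungAgeEquation":
        return cls(
            sex=d["sex"],
            method=d["method"],
            intercept=float(d["intercept"]),
            linear_terms={k: float(v) for k, v in d["linear_terms"].items()},
            knots=KnotSet.from_dict(d["knots"]) if d.get("knots") else None,
            spline_coefficients=(
                tuple(float(c) for c in d["spline_coefficients"])
                if d.get("spline_coefficients") is not None
                else None
            ),
            breakpoint=d.get("breakpoint"),
            hinge_coefficient=d.get("hinge_coefficient"),
            training_ranges=(
                {k: (float(v[0]), float(v[1])) for k, v in d["training_ranges"].items()}
                if d.get("training_ranges")
                else None
            ),
            model_id=d.get("model_id", ""),
        )


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    if isinstance(records, pd.Series):
        return records.to_frame().T
    if isinstance(records, Mapping):
        return pd.DataFrame([records])
    raise TypeError(f"records must be a DataFrame, Series or mapping, got {type(records)}")


def predict_lung_age(equation: LungAgeEquation, records):
    """Functional alias for :meth:`LungAgeEquation.predict`."""
    return equation.predict(records)


def delta_lung_age(lung_age, chronological_age):
    """Δ lung age (years) = lung age − chronological age."""
    lung_age = np.asarray(lung_age, dtype=float)
    chronological_age = np.asarray(chronological_age, dtype=float)
    if not (np.all(np.isfinite(lung_age)) and np.all(np.isfinite(chronological_age))):
        raise ValueError("ages must be finite")
    out = lung_age - chronological_age
    return float(out) if out.ndim == 0 else out


def delta_mse(deltas) -> float:
    """Mean squared Δ lung age (years²) — the external-validation error."""
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size == 0:
        raise ValueError("delta_mse of an empty sample is undefined")
    return float(np.mean(deltas**2))


def compute_delta(equation: LungAgeEquation, records: pd.DataFrame) -> pd.DataFrame:
    """Per-subject lung age and Δ lung age for a record table."""
    la = equation.predict(records)
    return pd.DataFrame(
        {
            "id": records["id"].to_numpy() if "id" in records else np.arange(len(records)),
            "age": records["age"].to_numpy(dtype=float),
            "lung_age": la,
            "delta": la - records["age"].to_numpy(dtype=float),
            "model_id": equation.model_id,
        }
    )


def load_published_model(
    sex: str,
    spline_coefficients=None,
    knots: KnotSet | None = None,
) -> LungAgeEquation:
    """Build the published sex-specific spline equation.

    The linear coefficients (intercept, height, FEF50%, FEF75%) are built in;
    the natural-spline FEV1 contribution was distributed separately and must
    be supplied as ``knots`` plus one coefficient per spline column.  Without
    it the equation cannot be evaluated, so this loader refuses to construct
    a silently wrong linear-only predictor.
    """
    if sex not in PUBLISHED_LINEAR_COEFFICIENTS:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if spline_coefficients is None or knots is None:
        raise ValueError(
            "published spline coefficients required: the ns(FEV1) knots and "
            "coefficients are distributed separately and must be supplied"
        )
    coefs = tuple(float(c) for c in np.asarray(spline_coefficients, dtype=float))
    if len(coefs) != knots.n_columns:
        raise ValueError(
            f"published spline coefficients required: got {len(coefs)} "
            f"coefficients for a {knots.n_columns}-column basis"
        )
    lin = PUBLISHED_LINEAR_COEFFICIENTS[sex]
    return LungAgeEquation(
        sex=sex,
        method="spline",
        intercept=lin["intercept"],
        linear_terms={"height": lin["height"], "fef50": lin["fef50"], "fef75": lin["fef75"]},
        knots=knots,
        spline_coefficients=coefs,
        model_id=f"published_spline_{sex}",
    )
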