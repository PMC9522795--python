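"""Healthy-subject inclusion filtering and propensity score matching.

Healthy reference subjects must be 18–80 years old, never-smokers, have
BMI ≤ 30 kg/m² and all of FEV1, FVC, FEV1/FVC and MMEF within normal
limits.  "Within normal limits" depends on external reference equations and
is therefore consumed as precomputed boolean flag columns, never computed
here.

Patient and healthy groups differ in age, height and sex, so comparisons
use propensity score matching: a logistic model of group membership on
those covariates, then greedy nearest-neighbour matching on the logit
without replacement, with a caliper of 0.2 × SD of the logit by default.
Balance is reported as standardized mean differences (SMD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "InclusionConfig",
    "MatchResult",
    "healthy_inclusion_filter",
    "propensity_match",
    "standardized_mean_difference",
]

NORMAL_FLAG_COLUMNS = ("fev1_normal", "fvc_normal", "fev1_fvc_normal", "mmef_normal")


@dataclass(frozen=True)
class InclusionConfig:
    """Active rules for the healthy-reference inclusion filter."""

    age_range: tuple[float, float] = (18.0, 80.0)
    bmi_max: float = 30.0
    require_normal_flags: bool = True
    require_nonsmoker: bool = True

    def __post_init__(self) -> None:
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError(f"age_range low must be < high, got {self.age_range}")
        if self.bmi_max <= 0:
            raise ValueError(f"bmi_max must be > 0, got {self.bmi_max}")


def healthy_inclusion_filter(
    records: pd.DataFrame, config: InclusionConfig = InclusionConfig()
):
    """Apply the healthy-subject inclusion rules.

    Returns ``(included, exclusions)`` where ``exclusions`` lists each
    excluded id with the *first* failed rule.  Raises if an active rule
    needs a column the table lacks.
    """
    lo, hi = config.age_range
    needed = ["age"]
    if config.bmi_max is not None:
        needed += ["weight", "height"]
    if config.require_nonsmoker:
        needed.append("smoker")
    if config.require_normal_flags:
        needed += list(NORMAL_FLAG_COLUMNS)
    missing = [c for c in needed if c not in records.columns]
    if missing:
        raise ValueError(
            f"inclusion filter needs missing column(s): {', '.join(missing)}"
        )

    reasons = pd.Series(pd.NA, index=records.index, dtype="object")

    def mark(mask: pd.Series, reason: str) -> None:
        sel = mask & reasons.isna()
        reasons[sel] = reason

    age = records["age"].astype(float)
    mark(age < lo, f"age<{lo:g}")
    mark(age > hi, f"age>{hi:g}")
    if config.bmi_max is not None:
        bmi = records["weight"].astype(float) / (records["height"].astype(float) / 100.0) ** 2
        mark(bmi > config.bmi_max, f"bmi>{config.bmi_max:g}")
    if config.require_nonsmoker:
        mark(records["smoker"].astype(bool), "smoker")
    if config.require_normal_flags:
        for col in NORMAL_FLAG_COLUMNS:
            mark(~records[col].astype(bool), f"{col}=False")

    excluded = reasons.notna()
    exclusions = pd.DataFrame(
        {
            "id": records.loc[excluded, "id"].to_numpy()
            if "id" in records.columns
            else records.index[excluded],
            "reason": reasons[excluded].to_numpy(),
        }
    )
    return records.loc[~excluded].copy(), exclusions


def standardized_mean_difference(group_a, group_b, kind: str = "continuous") -> float:
    """SMD between two groups; ``kind='binary'`` treats values as 0/1."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if kind == "binary":
        pa, pb = a.mean(), b.mean()
        pooled = np.sqrt((pa * (1 - pa) + pb * (1 - pb)) / 2.0)
        diff = pa - pb
    elif kind == "continuous":
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
        diff = a.mean() - b.mean()
    else:
        raise ValueError(f"kind must be 'continuous' or 'binary', got {kind!r}")
    if pooled == 0:
        if diff == 0:
            return 0.0
        warnings.warn(
            "zero pooled SD with unequal means; SMD is infinite",
            UserWarning,
            stacklevel=2,
        )
        return float(np.sign(diff) * np.inf)
    return float(diff / pooled)


@dataclass
class MatchResult:
    """Pairing and balance diagnostics from propensity score matching."""

    pairs: list[tuple]  # (case_id, control_id)
    case_ids: list
    control_ids: list
    propensity_logit: pd.Series  # indexed by id, both groups
    smd_pre: dict[str, float]
    smd_post: dict[str, float]
    caliper_width: float | None
    seed: int | None
    n_cases: int
    n_unmatched_cases: int

    def balance_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"smd_pre": self.smd_pre, "smd_post": self.smd_post}
        ).rename_axis("covariate")

    def pairs_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["case_id", "control_id"])


def _covariate_matrix(df: pd.DataFrame, covariates) -> np.ndarray:
    cols = []
    for c in covariates:
        if c == "sex":
            cols.append((df["sex"] == "male").to_numpy(dtype=float))
        else:
            cols.append(df[c].to_numpy(dtype=float))
    return np.column_stack(cols)


def propensity_match(
    cases: pd.DataFrame,
    controls: pd.DataFrame,
    covariates=("age", "height", "sex"),
    ratio: int = 1,
    caliper: float | None = 0.2,
    seed=None,
) -> MatchResult:
    """Greedy nearest-neighbour matching on the propensity logit.

    A logistic model of case status on ``covariates`` is fitted to the
    pooled sample; cases are visited in seeded random order and each takes
    up to ``ratio`` nearest unused controls within the caliper
    (``caliper × SD`` of the logit; ``caliper=None`` disables it).
    Controls are never reused.
    """
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("cases and controls must both be non-empty")
    for c in covariates:
        for df, name in ((cases, "cases"), (controls, "controls")):
            if c not in df.columns:
                raise ValueError(f"covariate {c!r} missing from {name}")
    if ratio < 1:
        raise ValueError(f"ratio must be >= 1, got {ratio}")

    pooled = pd.concat([cases, controls], ignore_index=True)
    y = np.concatenate([np.ones(len(cases)), np.zeros(len(controls))])
    X = sm.add_constant(_covariate_matrix(pooled, covariates))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise ValueError(
            "propensity model failed (complete or quasi-complete separation); "
            "consider caliper-free exact matching on the covariates instead"
        ) from exc
    if not fit.mle_retvals.get("converged", True) or np.abs(fit.params[1:]).max() > 50:
        raise ValueError(
            "propensity model did not converge (likely complete separation); "
            "consider caliper-free exact matching on the covariates instead"
        )
    logit = X @ fit.params

    ids = (
        pooled["id"].to_numpy()
        if "id" in pooled.columns
        else np.arange(len(pooled))
    )
    case_logit = logit[: len(cases)]
    control_logit = logit[len(cases):]
    case_ids = ids[: len(cases)]
    control_ids = ids[len(cases):]

    width = None
    if caliper is not None:
        width = float(caliper * np.std(logit, ddof=1))

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cases))
    available = np.ones(len(controls), dtype=bool)
    pairs: list[tuple] = []
    matched_case, matched_control = [], []
    n_unmatched = 0
    for i in order:
        got_any = False
        for _ in range(ratio):
            dist = np.abs(control_logit - case_logit[i])
            dist[~available] = np.inf
            j = int(np.argmin(dist))
            if not np.isfinite(dist[j]) or (width is not None and dist[j] > width):
                break
            available[j] = False
            pairs.append((case_ids[i], control_ids[j]))
            matched_control.append(control_ids[j])
            got_any = True
        if got_any:
            matched_case.append(case_ids[i])
        else:
            n_unmatched += 1

    matched_case_set = set(matched_case)
    matched_control_set = set(matched_control)
    cases_m = cases.loc[[cid in matched_case_set for cid in case_ids]]
    controls_m = controls.loc[[cid in matched_control_set for cid in control_ids]]

    def smds(ca: pd.DataFrame, co: pd.DataFrame) -> dict[str, float]:
        out = {}
        for c in covariates:
            kind = "binary" if c == "sex" else "continuous"
            a = (ca[c] == "male").astype(float) if c == "sex" else ca[c].astype(float)
            b = (co[c] == "male").astype(float) if c == "sex" else co[c].astype(float)
            out[c] = standardized_mean_difference(a, b, kind)
        return out

    smd_post = (
        smds(cases_m, controls_m)
        if len(cases_m) and len(controls_m)
        else {c: float("nan") for c in covariates}
    )
    return MatchResult(
        pairs=pairs,
        case_ids=list(matched_case),
        control_ids=list(matched_control),
        propensity_logit=pd.Series(logit, index=ids, name="logit"),
        smd_pre=smds(cases, controls),
        smd_post=smd_post,
        caliper_width=width,
        seed=seed,
        n_cases=len(cases),
        n_unmatched_cases=n_unmatched,
    )
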