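"""Backward-age regression models: MLR, piecewise-linear and natural-spline.

The response is chronological age (years) of healthy subjects; explanatory
variables are height and spirometric parameters.  Models are sex-specific.
Three families differ only in how FEV1 enters:

* ``mlr`` — a single linear FEV1 coefficient;
* ``piecewise`` — one continuous breakpoint in FEV1, chosen by minimum
  residual sum of squares over a grid of FEV1 quantiles;
* ``spline`` — natural cubic spline columns in FEV1 (knots at quantiles of
  the fitting sample unless supplied).

`LungAgeModel` holds data + configuration; ``fit()`` returns a
`LungAgeResults` carrying OLS estimates, t-based 95% intervals, fit
statistics (R², adjusted R², RSE, MSE) and the portable `LungAgeEquation`.
Model comparison uses adjusted R², the criterion used to pick the final
published equation; `enumerate_and_select` fits a candidate grid and keeps
the per-sex winner.  `bootstrap_validate` refits on subject-level resamples
for internal validation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .basis import KnotSet, natural_cubic_basis, place_knots
from .equation import LungAgeEquation

__all__ = [
    "FitStats",
    "LungAgeModel",
    "LungAgeResults",
    "BootstrapReport",
    "SelectionResult",
    "adjusted_r2",
    "fit_mlr_lung_age",
    "fit_piecewise_lung_age",
    "fit_spline_lung_age",
    "enumerate_and_select",
    "bootstrap_validate",
]

ALLOWED_PREDICTORS = ("height", "fvc", "fev1_fvc", "mmef", "fef50", "fef75")
DEFAULT_PREDICTORS = ("height", "fef50", "fef75")
_METHOD_ORDER = {"mlr": 0, "piecewise": 1, "spline": 2}


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted coefficient of determination, 1 − (1 − R²)(n − 1)/(n − p − 1)."""
    if n <= p + 1:
        raise ValueError(f"adjusted R² requires n > p + 1 (n={n}, p={p})")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


@dataclass(frozen=True)
class FitStats:
    """Goodness-of-fit summary of a backward-age regression."""

    r2: float
    adj_r2: float
    rse: float  # residual standard error, years
    mse: float  # mean squared error, years²
    n: int
    p: int  # predictors, excluding intercept

    def to_dict(self) -> dict:
        return {
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "rse": self.rse,
            "mse": self.mse,
            "n": self.n,
            "p": self.p,
        }


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # constant non-intercept columns are the usual culprit; otherwise
        # blame the pivoted-QR trailing columns (never the intercept)
        constant = [
            names[j]
            for j in range(1, X.shape[1])
            if np.ptp(X[:, j]) == 0
        ]
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        trailing = [names[j] for j in piv[rank:] if names[j] != "intercept"]
        bad = sorted(set(constant) | set(trailing)) or sorted(names[j] for j in piv[rank:])
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear column(s): {', '.join(bad)}"
        )


def _ols(y: np.ndarray, X: np.ndarray, names: list[str]):
    n, k = X.shape
    p = k - 1
    if n <= k:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    _check_rank(X, names)
    res = sm.OLS(y, X).fit()
    rss = float(res.ssr)
    r2 = float(res.rsquared)
    stats_ = FitStats(
        r2=r2,
        adj_r2=adjusted_r2(r2, n, p),
        rse=float(np.sqrt(rss / (n - k))),
        mse=rss / n,
        n=n,
        p=p,
    )
    return res, stats_


class LungAgeModel:
    """Sex-specific backward-age model specification bound to data.

    Parameters
    ----------
    data:
        Record table with columns ``age``, ``fev1`` and the requested
        predictors; a ``sex`` column is used to restrict to ``sex``.
    sex:
        ``"male"`` or ``"female"``.
    method:
        ``"mlr"``, ``"piecewise"`` or ``"spline"``.
    predictors:
        Linear covariates besides FEV1, drawn from
        ``{height, fvc, fev1_fvc, mmef, fef50, fef75}``.
    knots:
        Optional explicit `KnotSet` for the spline method; otherwise knots
        are placed at quantiles of the fitting sample
        (``n_interior_knots`` interior knots, boundaries at
        ``boundary_quantiles``).
    breakpoint_grid:
        Optional explicit FEV1 breakpoint candidates for the piecewise
        method; defaults to the 5th–95th percentile grid in 1-percentile
        steps.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        sex: str,
        method: str = "spline",
        predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
        knots: KnotSet | None = None,
        n_interior_knots: int = 3,
        boundary_quantiles: tuple[float, float] = (0.05, 0.95),
        breakpoint_grid=None,
    ):
        if sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
        if method not in _METHOD_ORDER:
            raise ValueError(f"unknown method {method!r}")
        bad = set(predictors) - set(ALLOWED_PREDICTORS)
        if bad:
            raise ValueError(
                f"predictors {sorted(bad)} not in allowed set {ALLOWED_PREDICTORS}"
            )
        if "sex" in data.columns:
            data = data.loc[data["sex"] == sex]
        if len(data) == 0:
            raise ValueError(f"no records for sex={sex!r}")
        needed = {"age", "fev1", *predictors}
        missing = sorted(needed - set(data.columns))
        if missing:
            raise ValueError(f"missing column(s): {', '.join(missing)}")
        self.data = data.reset_index(drop=True)
        self.sex = sex
        self.method = method
        self.predictors = tuple(predictors)
        self.knots = knots
        self.n_interior_knots = n_interior_knots
        self.boundary_quantiles = boundary_quantiles
        self.breakpoint_grid = breakpoint_grid

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, sex: str, **kwargs) -> "LungAgeModel":
        return cls(data, sex, **kwargs)

    # -- design construction ---------------------------------------------
    def _linear_block(self, df: pd.DataFrame):
        names = ["intercept", *self.predictors]
        cols = [np.ones(len(df))] + [df[p].to_numpy(dtype=float) for p in self.predictors]
        return names, cols

    def _design(self, df: pd.DataFrame, knots: KnotSet | None = None, breakpoint=None):
        names, cols = self._linear_block(df)
        fev1 = df["fev1"].to_numpy(dtype=float)
        if self.method == "mlr":
            names.append("fev1")
            cols.append(fev1)
        elif self.method == "piecewise":
            names += ["fev1", "fev1_hinge"]
            cols += [fev1, np.maximum(fev1 - breakpoint, 0.0)]
        else:
            basis = natural_cubic_basis(fev1, knots)
            for j in range(basis.shape[1]):
                names.append(f"ns_fev1_{j + 1}")
                cols.append(basis[:, j])
        return names, np.column_stack(cols)

    def _resolve_knots(self, fev1: np.ndarray) -> KnotSet:
        if self.knots is not None:
            return self.knots
        return place_knots(fev1, self.n_interior_knots, self.boundary_quantiles)

    def _resolve_grid(self, fev1: np.ndarray) -> np.ndarray:
        if self.breakpoint_grid is not None:
            grid = np.asarray(self.breakpoint_grid, dtype=float)
            if grid.min() < fev1.min() or grid.max() > fev1.max():
                raise ValueError(
                    "breakpoint grid extends outside the observed FEV1 range "
                    f"[{fev1.min():.4g}, {fev1.max():.4g}]"
                )
            return grid
        qs = np.arange(0.05, 0.9501, 0.01)
        return np.unique(np.quantile(fev1, qs))

    # -- fitting -----------------------------------------------------------
    def fit(self) -> "LungAgeResults":
        df = self.data
        y = df["age"].to_numpy(dtype=float)
        fev1 = df["fev1"].to_numpy(dtype=float)
        knots = breakpoint = None
        if self.method == "spline":
            knots = self._resolve_knots(fev1)
            names, X = self._design(df, knots=knots)
            res, fit_stats = _ols(y, X, names)
        elif self.method == "piecewise":
            grid = self._resolve_grid(fev1)
            best = None
            for bp in grid:
                names, X = self._design(df, breakpoint=bp)
                if np.linalg.matrix_rank(X) < X.shape[1]:
                    continue  # e.g. hinge identically zero at the extreme grid point
                cand = sm.OLS(y, X).fit()
                if best is None or cand.ssr < best[1].ssr:
                    best = (bp, cand, names, X)
            if best is None:
                raise ValueError("no breakpoint candidate produced a full-rank design")
            breakpoint, res, names, X = best
            n, k = X.shape
            fit_stats = FitStats(
                r2=float(res.rsquared),
                adj_r2=adjusted_r2(float(res.rsquared), n, k - 1),
                rse=float(np.sqrt(res.ssr / (n - k))),
                mse=float(res.ssr) / n,
                n=n,
                p=k - 1,
            )
        else:
            names, X = self._design(df)
            res, fit_stats = _ols(y, X, names)

        params = pd.Series(res.params, index=names)
        ci = pd.DataFrame(res.conf_int(0.05), index=names, columns=["low", "high"])
        bse = pd.Series(res.bse, index=names)

        training_ranges = {
            c: (float(df[c].min()), float(df[c].max()))
            for c in ("fev1", *self.predictors)
        }
        linear_terms = {p: float(params[p]) for p in self.predictors}
        spline_coefs = None
        hinge = None
        if self.method == "mlr":
            linear_terms["fev1"] = float(params["fev1"])
        elif self.method == "piecewise":
            linear_terms["fev1"] = float(params["fev1"])
            hinge = float(params["fev1_hinge"])
        else:
            spline_coefs = tuple(
                float(params[f"ns_fev1_{j + 1}"]) for j in range(knots.n_columns)
            )
        equation = LungAgeEquation(
            sex=self.sex,
            method=self.method,
            intercept=float(params["intercept"]),
            linear_terms=linear_terms,
            knots=knots,
            spline_coefficients=spline_coefs,
            breakpoint=float(breakpoint) if breakpoint is not None else None,
            hinge_coefficient=hinge,
            training_ranges=training_ranges,
        )
        return LungAgeResults(
            model=self,
            equation=equation,
            params=params,
            bse=bse,
            conf_int=ci,
            fit_stats=fit_stats,
            resid=pd.Series(res.resid, name="resid"),
        )


@dataclass
class LungAgeResults:
    """Fitted backward-age model: estimates, uncertainty and diagnostics."""

    model: LungAgeModel
    equation: LungAgeEquation
    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame
    fit_stats: FitStats
    resid: pd.Series

    @property
    def breakpoint_slopes(self) -> tuple[float, float] | None:
        """(left, right) FEV1 slopes for the piecewise method."""
        if self.equation.breakpoint is None:
            return None
        left = self.equation.linear_terms["fev1"]
        return left, left + self.equation.hinge_coefficient

    def predict(self, records=None) -> np.ndarray:
        if records is None:
            records = self.model.data
        return self.equation.predict(records)

    def bootstrap(self, B: int = 1000, seed=None) -> "BootstrapReport":
        return bootstrap_validate(self.model, B=B, seed=seed)

    def summary(self) -> str:
        fs = self.fit_stats
        lines = [
            f"Lung age estimation equation ({self.model.method}, {self.model.sex})",
            f"  n = {fs.n}, predictors = {fs.p}",
            f"  R² = {fs.r2:.4g}   adjusted R² = {fs.adj_r2:.4g}",
            f"  RSE = {fs.rse:.4g} years   MSE = {fs.mse:.4g} years²",
            "",
            f"  {'term':<14}{'coef':>10}  {'95% CI':>22}",
        ]
        for name in self.params.index:
            lo, hi = self.conf_int.loc[name]
            lines.append(
                f"  {name:<14}{self.params[name]:>10.4g}  "
                f"({lo:>9.4g}, {hi:>9.4g})"
            )
        if self.equation.breakpoint is not None:
            left, right = self.breakpoint_slopes
            lines.append(
                f"  FEV1 breakpoint at {self.equation.breakpoint:.4g} L; "
                f"slopes {left:.4g} (left) / {right:.4g} (right)"
            )
        if self.equation.knots is not None:
            lines.append(f"  spline knots: {self.equation.knots.all_knots.round(4).tolist()}")
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Observed vs fitted chronological age (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        y = self.model.data["age"].to_numpy(dtype=float)
        ax.scatter(y, self.predict(), s=8, alpha=0.4)
        lims = [y.min(), y.max()]
        ax.plot(lims, lims, color="k", lw=1)
        ax.set_xlabel("chronological age (years)")
        ax.set_ylabel("predicted lung age (years)")
        ax.set_title(f"{self.model.method} ({self.model.sex})")
        return ax


# -- convenience constructors mirroring the three model families ----------
def fit_mlr_lung_age(records, predictors=DEFAULT_PREDICTORS, sex="male", **kw) -> LungAgeResults:
    return LungAgeModel(records, sex, method="mlr", predictors=predictors, **kw).fit()


def fit_piecewise_lung_age(
    records, predictors=DEFAULT_PREDICTORS, sex="male", breakpoint_grid=None, **kw
) -> LungAgeResults:
    return LungAgeModel(
        records, sex, method="piecewise", predictors=predictors,
        breakpoint_grid=breakpoint_grid, **kw,
    ).fit()


def fit_spline_lung_age(records, predictors=DEFAULT_PREDICTORS, sex="male", **kw) -> LungAgeResults:
    return LungAgeModel(records, sex, method="spline", predictors=predictors, **kw).fit()


def default_candidate_subsets(max_terms: int = 5) -> list[tuple[str, ...]]:
    """All subsets of the optional covariates, capped at ``max_terms`` total
    terms counting the always-present FEV1 effect as one."""
    out = []
    for r in range(0, max_terms):
        out.extend(itertools.combinations(ALLOWED_PREDICTORS, r))
    return out


@dataclass
class SelectionResult:
    """Outcome of fitting a candidate grid and keeping the per-sex winner."""

    best: dict[str, LungAgeResults]
    ranking: pd.DataFrame
    failures: list[dict]


def enumerate_and_select(
    records: pd.DataFrame,
    candidate_subsets=None,
    methods=("mlr", "piecewise", "spline"),
    sexes=("male", "female"),
    **model_kwargs,
) -> SelectionResult:
    """Fit every (predictor subset × method × sex) candidate and select the
    maximum-adjusted-R² model per sex.

    Ties are broken towards parsimony (fewer parameters), then by the fixed
    method order mlr < piecewise < spline.  Candidates that fail to fit are
    skipped and logged unless every candidate for a sex fails.
    """
    if candidate_subsets is None:
        candidate_subsets = default_candidate_subsets()
    candidate_subsets = list(candidate_subsets)
    if not candidate_subsets:
        raise ValueError("at least one candidate predictor subset is required")
    unknown = [m for m in methods if m not in _METHOD_ORDER]
    if unknown:
        raise ValueError(f"unknown method(s): {unknown}")

    rows, failures, best = [], [], {}
    fits: dict[tuple, LungAgeResults] = {}
    for sex in sexes:
        for subset in candidate_subsets:
            for method in methods:
                try:
                    res = LungAgeModel(
                        records, sex, method=method, predictors=tuple(subset),
                        **model_kwargs,
                    ).fit()
                except Exception as exc:  # noqa: BLE001 — skip-and-log per spec
                    failures.append(
                        {"sex": sex, "method": method, "predictors": subset,
                         "error": str(exc)}
                    )
                    continue
                key = (sex, method, tuple(subset))
                fits[key] = res
                rows.append(
                    {
                        "sex": sex,
                        "method": method,
                        "predictors": "+".join(subset) if subset else "(fev1 only)",
                        "p": res.fit_stats.p,
                        "r2": res.fit_stats.r2,
                        "adj_r2": res.fit_stats.adj_r2,
                        "rse": res.fit_stats.rse,
                        "_key": key,
                    }
                )
    if not rows:
        raise ValueError(f"all candidates failed; first error: {failures[0]['error']}")

    ranking = pd.DataFrame(rows)
    ranking["_adj_r2_key"] = ranking["adj_r2"].round(12)
    ranking = ranking.sort_values(
        by=["sex", "_adj_r2_key", "p", "method"],
        ascending=[True, False, True, True],
        key=lambda col: col.map(_METHOD_ORDER) if col.name == "method" else col,
    ).reset_index(drop=True)
    ranking["selected"] = False
    for sex in sexes:
        sub = ranking.loc[ranking["sex"] == sex]
        if len(sub) == 0:
            raise ValueError(f"all candidates failed for sex={sex!r}")
        idx = sub.index[0]
        ranking.loc[idx, "selected"] = True
        best[sex] = fits[ranking.loc[idx, "_key"]]
    ranking = ranking.drop(columns=["_key", "_adj_r2_key"])
    return SelectionResult(best=best, ranking=ranking, failures=failures)


@dataclass
class BootstrapReport:
    """Internal validation by subject-level bootstrap resampling."""

    B: int
    seed: int | None
    n_failed: int
    coefficients: pd.DataFrame  # mean, sd, 2.5%, 97.5% per coefficient
    adj_r2_summary: dict
    mse_summary: dict

    def to_frame(self) -> pd.DataFrame:
        extra = pd.DataFrame(
            [self.adj_r2_summary, self.mse_summary], index=["adj_r2", "mse"]
        )
        return pd.concat([self.coefficients, extra])


def _summarize(values: np.ndarray) -> dict:
    return {
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
        "q025": float(np.quantile(values, 0.025)),
        "q975": float(np.quantile(values, 0.975)),
    }


def bootstrap_validate(model: LungAgeModel, B: int = 1000, seed=None) -> BootstrapReport:
    """Refit the model on ``B`` with-replacement resamples of its subjects.

    Replicates whose resample yields a rank-deficient design are skipped and
    counted.  Fully reproducible given ``seed``.
    """
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    rng = np.random.default_rng(seed)
    n = len(model.data)
    # freeze the primary fit's knots so spline coefficients are comparable
    # across replicates
    frozen_knots = (
        model._resolve_knots(model.data["fev1"].to_numpy(dtype=float))
        if model.method == "spline"
        else None
    )
    coef_draws, adj_draws, mse_draws = [], [], []
    n_failed = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        resampled = model.data.iloc[idx].reset_index(drop=True)
        try:
            res = LungAgeModel(
                resampled,
                model.sex,
                method=model.method,
                predictors=model.predictors,
                knots=frozen_knots,
                n_interior_knots=model.n_interior_knots,
                boundary_quantiles=model.boundary_quantiles,
                breakpoint_grid=model.breakpoint_grid,
            ).fit()
        except ValueError:
            n_failed += 1
            continue
        coef_draws.append(res.params)
        adj_draws.append(res.fit_stats.adj_r2)
        mse_draws.append(res.fit_stats.mse)
    if not coef_draws:
        raise ValueError("every bootstrap replicate failed to fit")
    coefs = pd.DataFrame(coef_draws)
    summary = pd.DataFrame({name: _summarize(coefs[name].to_numpy()) for name in coefs}).T
    return BootstrapReport(
        B=B,
        seed=seed,
        n_failed=n_failed,
        coefficients=summary,
        adj_r2_summary=_summarize(np.asarray(adj_draws)),
        mse_summary=_summarize(np.asarray(mse_draws)),
    )
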