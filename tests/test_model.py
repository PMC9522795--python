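"""Backward-age regression: fitting, selection, bootstrap validation."""

import numpy as np
import pandas as pd
import pytest

from lungage.model import (
    LungAgeModel,
    adjusted_r2,
    bootstrap_validate,
    enumerate_and_select,
    fit_piecewise_lung_age,
)

from conftest import make_linear_records


class TestAdjustedR2:
    @pytest.mark.parametrize(
        "r2,n,p,expected",
        [
            (0.5, 12, 1, 0.45),
            (1.0, 100, 7, 1.0),
            (0.0, 10, 2, 1 - 9 / 7),
        ],
    )
    def test_formula(self, r2, n, p, expected):
        assert adjusted_r2(r2, n, p) == pytest.approx(expected, abs=1e-12)

    def test_decreasing_in_p(self):
        vals = [adjusted_r2(0.8, 50, p) for p in range(1, 10)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n > p"):
            adjusted_r2(0.5, 3, 2)


class TestMlr:
    def test_exact_recovery_on_noiseless_linear_data(self):
        df = make_linear_records(n=200, seed=1)
        res = LungAgeModel(df, "male", method="mlr").fit()
        assert res.fit_stats.r2 == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(
            [res.params["intercept"], res.params["height"], res.params["fev1"],
             res.params["fef50"], res.params["fef75"]],
            [10.0, 0.2, -6.0, 1.5, -4.0],
            atol=1e-8,
        )
        np.testing.assert_allclose(res.predict(), df["age"], atol=1e-8)

    def test_noise_coefficient_recovery_within_3se(self):
        df = make_linear_records(n=10_000, seed=2)
        r = np.random.default_rng(3)
        df["age"] = df["age"] + r.normal(0, 8.0, len(df))
        res = LungAgeModel(df, "male", method="mlr").fit()
        truth = {"intercept": 10.0, "height": 0.2, "fev1": -6.0, "fef50": 1.5, "fef75": -4.0}
        for name, true_val in truth.items():
            assert abs(res.params[name] - true_val) <= 3 * res.bse[name]

    def test_null_model_adj_r2_near_zero(self):
        df = make_linear_records(n=5000, seed=4)
        df["age"] = np.random.default_rng(5).normal(50, 10, len(df))
        res = LungAgeModel(df, "male", method="mlr").fit()
        assert abs(res.fit_stats.adj_r2) < 0.02

    def test_constant_predictor_raises_rank_error(self):
        df = make_linear_records(n=100, seed=6)
        df["fef75"] = 2.0
        with pytest.raises(ValueError, match="fef75"):
            LungAgeModel(df, "male", method="mlr").fit()

    def test_sexes_fit_independently(self, healthy_cohort):
        m = LungAgeModel(healthy_cohort, "male", method="mlr").fit()
        f = LungAgeModel(healthy_cohort, "female", method="mlr").fit()
        assert m.fit_stats.n + f.fit_stats.n == len(healthy_cohort)
        assert not np.allclose(m.params.to_numpy(), f.params.to_numpy())

    def test_empty_sex_stratum_rejected(self, male_cohort):
        with pytest.raises(ValueError, match="female"):
            LungAgeModel(male_cohort, "female", method="mlr")


class TestPiecewise:
    @staticmethod
    def two_segment_records(n=400, bp=3.0, left=2.0, right=-5.0, seed=0):
        r = np.random.default_rng(seed)
        fev1 = np.sort(r.uniform(1.0, 5.0, n))
        age = 40 + left * np.minimum(fev1, bp) + right * np.maximum(fev1 - bp, 0.0)
        return pd.DataFrame(
            {
                "id": np.arange(n).astype(str), "sex": "male", "age": age,
                "height": 170.0 + 0 * fev1, "fev1": fev1, "fvc": fev1 / 0.8,
                "fev1_fvc": 0.8, "mmef": 3.0, "fef50": 4.0, "fef75": 1.5,
            }
        )

    def test_noiseless_breakpoint_and_slopes_recovered(self):
        df = self.two_segment_records()
        grid = np.linspace(1.5, 4.5, 301)
        res = fit_piecewise_lung_age(df, predictors=(), sex="male", breakpoint_grid=grid)
        assert res.equation.breakpoint == pytest.approx(3.0, abs=(grid[1] - grid[0]))
        left, right = res.breakpoint_slopes
        assert left == pytest.approx(2.0, abs=0.05)
        assert right == pytest.approx(-5.0, abs=0.05)

    def test_grid_search_matches_brute_force_oracle(self):
        df = self.two_segment_records(seed=7)
        df["age"] = df["age"] + np.random.default_rng(8).normal(0, 2, len(df))
        model = LungAgeModel(df, "male", method="piecewise", predictors=())
        res = model.fit()
        # brute force: refit OLS at every grid point, track minimum RSS
        fev1 = df["fev1"].to_numpy()
        y = df["age"].to_numpy()
        best_bp, best_rss = None, np.inf
        for bp in model._resolve_grid(fev1):
            X = np.column_stack([np.ones(len(df)), fev1, np.maximum(fev1 - bp, 0)])
            if np.linalg.matrix_rank(X) < 3:
                continue
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(((y - X @ beta) ** 2).sum())
            if rss < best_rss:
                best_bp, best_rss = bp, rss
        assert res.equation.breakpoint == pytest.approx(best_bp)
        rss_fit = float((res.resid**2).sum())
        assert rss_fit == pytest.approx(best_rss, rel=1e-10)

    def test_single_global_slope_gives_equal_slopes(self):
        df = self.two_segment_records(bp=3.0, left=-4.0, right=-4.0)
        res = fit_piecewise_lung_age(df, predictors=(), sex="male")
        left, right = res.breakpoint_slopes
        assert left == pytest.approx(right, abs=1e-6)

    def test_prediction_continuous_at_breakpoint(self, male_cohort):
        res = LungAgeModel(male_cohort, "male", method="piecewise").fit()
        bp = res.equation.breakpoint
        rec = male_cohort.iloc[[0]].copy()
        lo, hi = rec.assign(fev1=bp - 1e-12), rec.assign(fev1=bp + 1e-12)
        assert abs(res.equation.predict(lo)[0] - res.equation.predict(hi)[0]) <= 1e-9

    def test_grid_outside_data_range_rejected(self, male_cohort):
        with pytest.raises(ValueError, match="outside"):
            LungAgeModel(
                male_cohort, "male", method="piecewise", breakpoint_grid=[0.01, 99.0]
            ).fit()


class TestSpline:
    def test_r2_at_least_mlr_on_same_covariates(self, healthy_cohort):
        """Nesting: the spline span contains the linear FEV1 term."""
        for sex in ("male", "female"):
            mlr = LungAgeModel(healthy_cohort, sex, method="mlr").fit()
            spl = LungAgeModel(healthy_cohort, sex, method="spline").fit()
            assert spl.fit_stats.r2 >= mlr.fit_stats.r2 - 1e-12

    def test_curve_recovery_on_nonlinear_truth(self):
        r = np.random.default_rng(9)
        n = 3000
        fev1 = r.uniform(1.2, 5.5, n)
        g = 90 - 25 * np.sqrt(fev1)  # smooth nonlinear age–FEV1 relation
        height = r.uniform(150, 190, n)
        age = g + 0.1 * (height - 170) + r.normal(0, 8, n)
        df = pd.DataFrame(
            {
                "id": np.arange(n).astype(str), "sex": "male", "age": age,
                "height": height, "fev1": fev1, "fvc": fev1 / 0.8, "fev1_fvc": 0.8,
                "mmef": 3.0 + 0 * fev1, "fef50": 4.0, "fef75": 1.5,
            }
        )
        res = LungAgeModel(df, "male", method="spline", predictors=("height",)).fit()
        grid = np.linspace(1.8, 4.8, 25)
        probe = pd.DataFrame(
            {"sex": "male", "fev1": grid, "height": 170.0}
        )
        pred = res.equation.predict(probe)
        true = 90 - 25 * np.sqrt(grid)
        # pointwise tolerance ~3x the OLS curve SE at n=3000, sigma=8
        assert np.abs(pred - true).max() < 2.5

    def test_explicit_knots_respected(self, male_cohort):
        from lungage.basis import KnotSet

        ks = KnotSet(2.2, 4.8, (3.0, 3.6, 4.1))
        res = LungAgeModel(male_cohort, "male", method="spline", knots=ks).fit()
        assert res.equation.knots == ks


class TestSelection:
    def test_argmax_by_adjusted_r2(self, healthy_cohort):
        sel = enumerate_and_select(
            healthy_cohort,
            candidate_subsets=[("height", "fef50", "fef75")],
            methods=("mlr", "spline"),
            sexes=("male",),
        )
        best = sel.best["male"]
        assert best.fit_stats.adj_r2 == sel.ranking["adj_r2"].max()
        assert sel.ranking.loc[sel.ranking["selected"], "method"].iloc[0] == best.model.method

    def test_tie_broken_by_parsimony_then_method_order(self):
        df = make_linear_records(n=400, seed=11)
        # noiseless linear truth: every family fits exactly (R² = 1); ties
        # must resolve to fewest parameters, then mlr < piecewise < spline
        sel = enumerate_and_select(
            df,
            candidate_subsets=[("height", "fef50", "fef75"),
                               ("height", "fvc", "fef50", "fef75")],
            methods=("spline", "piecewise", "mlr"),
            sexes=("male",),
        )
        best = sel.best["male"]
        assert best.model.method == "mlr"
        assert best.model.predictors == ("height", "fef50", "fef75")

    def test_failures_logged_not_fatal(self, male_cohort):
        df = male_cohort.copy()
        df["mmef"] = 1.0  # constant → rank-deficient candidate
        sel = enumerate_and_select(
            df,
            candidate_subsets=[("mmef",), ("height",)],
            methods=("mlr",),
            sexes=("male",),
        )
        assert len(sel.failures) == 1
        assert "mmef" in sel.failures[0]["error"]
        assert sel.best["male"].model.predictors == ("height",)

    def test_no_candidates_rejected(self, male_cohort):
        with pytest.raises(ValueError, match="at least one"):
            enumerate_and_select(male_cohort, candidate_subsets=[])


class TestBootstrap:
    def test_noiseless_data_reproduces_primary_exactly(self):
        df = make_linear_records(n=150, seed=12)
        model = LungAgeModel(df, "male", method="mlr")
        primary = model.fit()
        report = bootstrap_validate(model, B=20, seed=0)
        np.testing.assert_allclose(
            report.coefficients["mean"].to_numpy(),
            primary.params[report.coefficients.index].to_numpy(),
            atol=1e-7,
        )
        assert report.coefficients["sd"].max() < 1e-7

    def test_same_seed_reproducible(self, male_cohort):
        model = LungAgeModel(male_cohort, "male", method="mlr")
        r1 = bootstrap_validate(model, B=25, seed=99)
        r2 = bootstrap_validate(model, B=25, seed=99)
        pd.testing.assert_frame_equal(r1.coefficients, r2.coefficients)
        assert r1.adj_r2_summary == r2.adj_r2_summary

    def test_bootstrap_means_near_primary(self, male_cohort):
        model = LungAgeModel(male_cohort, "male", method="spline")
        primary = model.fit()
        report = bootstrap_validate(model, B=200, seed=7)
        for name in primary.params.index:
            se = report.coefficients.loc[name, "sd"]
            assert abs(report.coefficients.loc[name, "mean"] - primary.params[name]) <= 2 * se

    def test_invalid_B_rejected(self, male_cohort):
        with pytest.raises(ValueError, match="B"):
            bootstrap_validate(LungAgeModel(male_cohort, "male"), B=0)
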