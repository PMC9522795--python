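"""ULN derivation, Δ classification, and airflow-limitation staging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungage.norms import (
    PUBLISHED_ULN_SPLINE,
    UlnModel,
    classify_delta,
    derive_age_dependent_uln,
    derive_constant_uln,
    exceedance_table,
    gold_stage,
    uln_at_age,
)
from lungage.synthetic import generate_delta_null


class TestUlnArithmetic:
    @pytest.mark.parametrize(
        "age,expected",
        [(50.0, 7.669), (18.0, 18.005), (80.0, -2.021)],
    )
    def test_published_formula_values(self, age, expected):
        """12.243 − 0.323·age + 1.645·7.037 at ages 50/18/80."""
        assert uln_at_age(PUBLISHED_ULN_SPLINE, age) == pytest.approx(expected, abs=5e-4)

    def test_negative_uln_is_legal_output(self):
        assert uln_at_age(PUBLISHED_ULN_SPLINE, 80.0) < 0

    def test_affine_in_age(self):
        u = PUBLISHED_ULN_SPLINE
        for a1, a2 in [(20, 70), (33.5, 61.2)]:
            assert u.uln_at_age(a1) - u.uln_at_age(a2) == pytest.approx(
                u.age_slope * (a1 - a2), abs=1e-12
            )

    def test_zero_slope_zero_rse_constant(self):
        u = UlnModel(5.0, 0.0, 0.0)
        assert u.uln_at_age(20) == u.uln_at_age(80) == 5.0

    def test_lln_symmetric(self):
        u = UlnModel(10.0, -0.2, 4.0)
        mid = u.intercept + u.age_slope * 40.0
        assert u.uln_at_age(40) - mid == pytest.approx(mid - u.lln_at_age(40))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            UlnModel(0, 0, -1.0)
        with pytest.raises(ValueError):
            UlnModel(0, 0, 1.0, z=0.0)


class TestDeriveUln:
    def test_parameter_recovery_at_published_values(self):
        ages, deltas = generate_delta_null(n=100_000, seed=123)
        u = derive_age_dependent_uln(deltas, ages)
        n = len(ages)
        sxx = ((ages - ages.mean()) ** 2).sum()
        se_slope = 7.037 / np.sqrt(sxx)
        se_int = 7.037 * np.sqrt(1 / n + ages.mean() ** 2 / sxx)
        assert abs(u.intercept - 12.243) <= 3 * se_int
        assert abs(u.age_slope - (-0.323)) <= 3 * se_slope
        assert abs(u.rse - 7.037) <= 3 * 7.037 / np.sqrt(2 * n)

    def test_exact_line_gives_zero_rse(self):
        ages = np.linspace(20, 70, 50)
        deltas = 3.0 - 0.1 * ages
        u = derive_age_dependent_uln(deltas, ages)
        assert u.rse == pytest.approx(0.0, abs=1e-10)
        assert u.uln_at_age(40.0) == pytest.approx(3.0 - 4.0, abs=1e-9)

    def test_constant_deltas_give_zero_slope(self):
        ages = np.linspace(20, 70, 40)
        u = derive_age_dependent_uln(np.full(40, 2.5), ages)
        assert u.age_slope == pytest.approx(0.0, abs=1e-12)
        assert u.uln_at_age(55.0) == pytest.approx(2.5, abs=1e-9)

    def test_constant_ages_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            derive_age_dependent_uln(np.arange(20.0), np.full(20, 50.0))

    def test_coverage_about_5_percent(self):
        """On the derivation sample itself ~5% of Δ exceed the ULN."""
        ages, deltas = generate_delta_null(n=3000, seed=7)
        u = derive_age_dependent_uln(deltas, ages)
        exceed = float(np.mean(deltas > u.uln_at_age(ages)))
        assert 0.035 <= exceed <= 0.065


class TestConstantUln:
    def test_interpolated_95th_percentile(self):
        assert derive_constant_uln(np.arange(1.0, 101.0)) == pytest.approx(95.05)

    def test_constant_sample(self):
        assert derive_constant_uln(np.full(30, 4.2)) == pytest.approx(4.2)

    def test_monotone_under_high_insertion(self):
        deltas = np.random.default_rng(0).normal(0, 5, 500)
        base = derive_constant_uln(deltas)
        grown = derive_constant_uln(np.append(deltas, base + 10))
        assert grown >= base

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_percentile_domain(self, bad):
        with pytest.raises(ValueError, match="percentile"):
            derive_constant_uln(np.arange(10.0), bad)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            derive_constant_uln([])


class TestClassification:
    def test_stage_iv_mean_delta_above_uln(self):
        # Δ = 65.43 at age 63.79 → ULN = 3.21, far exceeded
        assert classify_delta(65.43, 63.79, PUBLISHED_ULN_SPLINE) == "above_uln"

    def test_zero_delta_consistent(self):
        assert classify_delta(0.0, 40.0, PUBLISHED_ULN_SPLINE) == "consistent"

    def test_boundary_counts_as_within(self):
        age = 45.0
        lim = PUBLISHED_ULN_SPLINE.uln_at_age(age)
        assert classify_delta(lim, age, PUBLISHED_ULN_SPLINE) == "older_within_uln"
        assert classify_delta(lim + 1e-9, age, PUBLISHED_ULN_SPLINE) == "above_uln"

    def test_constant_mode_requires_constant(self):
        with pytest.raises(ValueError, match="constant"):
            classify_delta(5.0, 50.0, PUBLISHED_ULN_SPLINE, mode="constant")
        u = UlnModel(12.243, -0.323, 7.037, constant_uln=12.5)
        assert classify_delta(13.0, 50.0, u, mode="constant") == "above_uln"
        assert classify_delta(12.0, 50.0, u, mode="constant") == "older_within_uln"

    @settings(max_examples=200, deadline=None)
    @given(
        delta=st.floats(-80, 80, allow_nan=False),
        age=st.floats(18, 80, allow_nan=False),
    )
    def test_partition_every_pair_gets_exactly_one_label(self, delta, age):
        label = classify_delta(delta, age, PUBLISHED_ULN_SPLINE)
        assert label in {"consistent", "older_within_uln", "above_uln"}
        lim = PUBLISHED_ULN_SPLINE.uln_at_age(age)
        if delta <= 0:
            assert label == "consistent"
        elif delta <= lim:
            assert label == "older_within_uln"
        else:
            assert label == "above_uln"


class TestGoldStage:
    @pytest.mark.parametrize(
        "pct,expected",
        [
            (87.84, "I"), (80.0, "I"), (79.99, "II"), (65.0, "II"),
            (50.0, "II"), (49.99, "III"), (30.0, "III"), (29.9, "IV"), (1.0, "IV"),
        ],
    )
    def test_band_boundaries(self, pct, expected):
        assert gold_stage(pct) == expected

    def test_vectorized_partition(self):
        pcts = np.linspace(0.5, 130, 1000)
        labels = gold_stage(pcts)
        assert set(labels) == {"I", "II", "III", "IV"}
        # every value maps to exactly one stage and bands are ordered
        assert (labels[pcts >= 80] == "I").all()
        assert (labels[pcts < 30] == "IV").all()

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            gold_stage(0.0)
        with pytest.raises(ValueError, match="positive"):
            gold_stage(-5.0)


class TestExceedanceTable:
    def test_severe_cohort_fully_above_age_dependent_uln(self):
        rng = np.random.default_rng(0)
        severe = pd.DataFrame(
            {"delta": np.full(80, 60.0), "age": rng.uniform(60, 70, 80)}
        )
        tab = exceedance_table(
            {"stage_IV": severe},
            [("age_dependent", PUBLISHED_ULN_SPLINE, "age_dependent")],
        )
        assert tab.loc[0, "pct_over"] == 100.0

    def test_null_cohort_near_five_percent(self):
        ages, deltas = generate_delta_null(n=3000, seed=11)
        u = derive_age_dependent_uln(deltas, ages)
        tab = exceedance_table(
            {"healthy": pd.DataFrame({"delta": deltas, "age": ages})},
            [("age_dependent", u, "age_dependent")],
        )
        assert 3.5 <= tab.loc[0, "pct_over"] <= 6.5

    def test_empty_cohort_warns_and_zero_rows(self):
        with pytest.warns(UserWarning, match="empty"):
            tab = exceedance_table(
                {"none": pd.DataFrame(columns=["delta", "age"])},
                [("uln", PUBLISHED_ULN_SPLINE, "age_dependent")],
            )
        assert tab.loc[0, "n_total"] == 0

    def test_multiple_variants_cross_product(self):
        df = pd.DataFrame({"delta": [5.0, 20.0], "age": [50.0, 50.0]})
        u = UlnModel(12.243, -0.323, 7.037, constant_uln=12.5)
        tab = exceedance_table(
            {"a": df, "b": df},
            [("age_dep", u, "age_dependent"), ("const", u, "constant")],
        )
        assert len(tab) == 4
        assert set(tab["uln_variant"]) == {"age_dep", "const"}
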