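"""Stratification, regression models, diagnostics and sensitivity
analyses."""

import numpy as np
import pandas as pd
import pytest

from bmlpipe.analysis import (
    add_jsn_outcomes,
    classify_change,
    dichotomize_covariates,
    fit_jsn_models,
    fit_pain_models,
    fit_tertile_robust,
    linearity_check,
    medial_sensitivity,
    stratify_baseline_tertiles,
)
from bmlpipe.cohort import CohortSpec, generate_cohort


class TestStratification:
    def test_equal_split(self):
        labels, bounds = stratify_baseline_tertiles(np.arange(1, 10))
        assert np.bincount(labels).tolist() == [3, 3, 3]
        assert bounds[0] < bounds[1]

    def test_ties_go_lower(self):
        labels, bounds = stratify_baseline_tertiles(
            [1, 2, 3, 4, 5, 6, 7, 8, 9])
        at_cut = np.asarray([1, 2, 3, 4, 5, 6, 7, 8, 9]) == bounds[0]
        assert (labels[at_cut] == 0).all()

    def test_small_and_degenerate(self):
        with pytest.raises(ValueError):
            stratify_baseline_tertiles([1.0, 2.0])
        with pytest.warns(UserWarning, match="degenerate"):
            labels, _ = stratify_baseline_tertiles([2.0] * 9)
        assert (labels == 0).all()

    def test_tertile_bounds_near_study_pattern(self):
        df = generate_cohort(CohortSpec(n=4000, seed=5))
        _, bounds = stratify_baseline_tertiles(df["bml_total_base"])
        # study tertiles break near 1.0 and 2.7 cm^3
        assert bounds[0] == pytest.approx(1.0, abs=0.35)
        assert bounds[1] == pytest.approx(2.7, abs=0.45)


class TestChangeClasses:
    def test_symmetric_counts(self):
        rng = np.random.default_rng(0)
        c = rng.normal(0, 1, 400)
        labels, _ = classify_change(c)
        counts = pd.Series(labels).value_counts()
        assert abs(counts["regression"] - 100) <= 1
        assert abs(counts["minimal"] - 200) <= 2
        assert abs(counts["progression"] - 100) <= 1

    def test_supplied_study_cuts(self):
        labels, _ = classify_change([-1.1, 0.0, 1.0], cuts=(-0.8, 0.4))
        assert labels.tolist() == ["regression", "minimal", "progression"]

    def test_study_like_cuts_emerge(self):
        df = generate_cohort(CohortSpec(n=4000, seed=6))
        _, cuts = classify_change(df["bml_total_change"])
        assert cuts[0] == pytest.approx(-0.8, abs=0.25)
        assert cuts[1] == pytest.approx(0.4, abs=0.25)

    def test_too_few(self):
        with pytest.raises(ValueError):
            classify_change([1.0, 2.0, 3.0])


class TestDichotomize:
    def test_boundaries_and_missing(self):
        df = pd.DataFrame({"age": [64.9, 65.0, np.nan],
                           "bmi": [29.9, 30.0, np.nan]})
        out = dichotomize_covariates(df)
        assert out["age_ge65"].tolist()[:2] == [0.0, 1.0]
        assert out["bmi_ge30"].tolist()[:2] == [0.0, 1.0]
        assert np.isnan(out["age_ge65"].iloc[2])
        assert np.isnan(out["bmi_ge30"].iloc[2])


class TestPainModels:
    def test_three_models_report_terms(self):
        df = generate_cohort(CohortSpec(n=404, seed=0))
        res = fit_pain_models(df)
        assert set(res) == {"baseline_pain", "pain_change_baseline_bml",
                            "pain_change_bml_change"}
        for r in res.values():
            assert {"estimate", "se", "pvalue"} <= set(r.table.columns)
            assert r.n_used <= len(df)

    def test_rank_deficiency_named(self):
        df = generate_cohort(CohortSpec(n=100, seed=1)).copy()
        df["weight_kg"] = df["height_m"] * 2.0
        with pytest.raises(ValueError, match="collinear"):
            fit_pain_models(df)

    def test_missing_rows_dropped(self):
        df = generate_cohort(CohortSpec(n=200, seed=2)).copy()
        df.loc[:9, "weight_kg"] = np.nan
        res = fit_pain_models(df)["baseline_pain"]
        assert res.n_used == 190
        assert res.diagnostics["rows_missing"] == 10


class TestRobust:
    def test_outlier_resistance_vs_ols(self, rng):
        """With 10% gross outliers the robust slope beats OLS."""
        import statsmodels.api as sm
        n = 300
        x = rng.normal(0, 1.5, n)
        y = 0.8 * x + rng.normal(0, 1, n)
        y[:30] += rng.choice([-25, 25], 30)
        df = pd.DataFrame({
            "pain_change": y, "bml_total_change": x,
            "female": rng.binomial(1, 0.5, n),
            "weight_kg": rng.normal(85, 10, n),
            "height_m": rng.normal(1.7, 0.05, n),
            "age": rng.normal(63, 9, n)})
        res = fit_tertile_robust(df, np.zeros(n, dtype=int))[0]
        robust_err = abs(res.table.loc["bml_total_change", "estimate"] - 0.8)
        X = sm.add_constant(df[["bml_total_change", "female", "weight_kg",
                                "height_m", "age"]])
        ols_err = abs(sm.OLS(df["pain_change"], X).fit()
                      .params["bml_total_change"] - 0.8)
        assert robust_err < ols_err

    def test_agrees_with_ols_when_clean(self, rng):
        import statsmodels.api as sm
        n = 4000
        x = rng.normal(0, 2, n)
        y = 0.5 * x + rng.normal(0, 1, n)
        df = pd.DataFrame({
            "pain_change": y, "bml_total_change": x,
            "female": rng.binomial(1, 0.5, n),
            "weight_kg": rng.normal(85, 10, n),
            "height_m": rng.normal(1.7, 0.05, n),
            "age": rng.normal(63, 9, n)})
        rob = fit_tertile_robust(df, np.zeros(n, dtype=int))[0] \
            .table.loc["bml_total_change", "estimate"]
        X = sm.add_constant(df[["bml_total_change", "female", "weight_kg",
                                "height_m", "age"]])
        ols = sm.OLS(df["pain_change"], X).fit().params["bml_total_change"]
        assert rob == pytest.approx(ols, rel=0.02)

    def test_small_tertile_skipped(self):
        df = generate_cohort(CohortSpec(n=40, seed=3))
        labels = np.zeros(40, dtype=int)
        labels[:5] = 2
        with pytest.warns(UserWarning, match="skipped"):
            res = fit_tertile_robust(df, labels)
        assert 2 not in res


class TestJSNModels:
    def test_single_binary_predictor_matches_cross_product(self, rng):
        """Unadjusted logistic OR equals ad/bc to 4 decimals."""
        import statsmodels.api as sm
        a, b, c, d = 40, 60, 25, 75   # exposed events/non, unexposed
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        res = sm.Logit(y, sm.add_constant(x)).fit(disp=False)
        assert np.exp(res.params[1]) == pytest.approx(
            (a * d) / (b * c), abs=1e-4)

    def test_three_models_structure(self):
        df = generate_cohort(CohortSpec(n=375, seed=4))
        res = fit_jsn_models(df)
        m3 = res["progression_change_class"]
        assert res["baseline_jsn"].c_statistic > 0.5
        assert m3.overall_p is not None
        # grade-3 exclusion accounting: in = analyzed + grade3 + missing
        for m in (res["progression_baseline_bml"], m3):
            d = m.diagnostics
            assert d["rows_in"] == (d["rows_analyzed"]
                                    + d["rows_grade3_excluded"]
                                    + d["rows_missing"])

    def test_reference_class_or_is_one(self):
        df = generate_cohort(CohortSpec(n=375, seed=5))
        m3 = fit_jsn_models(df)["progression_change_class"]
        # the minimal class is the (omitted) reference: only the two
        # non-reference dummies appear
        assert {"class_regression", "class_progression"} \
            <= set(m3.table.index)
        assert "class_minimal" not in m3.table.index


class TestLinearity:
    def test_logit_linear_is_monotone(self, rng):
        n = 4000
        x = rng.normal(0, 1, n)
        p = 1 / (1 + np.exp(-(-0.5 + 0.8 * x)))
        y = rng.binomial(1, p)
        out = linearity_check(pd.DataFrame({"x": x, "y": y}), "x", "y")
        assert out["monotone"]
        spacings = np.diff(out["estimates"])
        assert (spacings > 0).all()

    def test_u_shape_flagged(self, rng):
        n = 4000
        x = rng.normal(0, 1, n)
        y = x**2 + rng.normal(0, 0.1, n)
        out = linearity_check(pd.DataFrame({"x": x, "y": y}), "x", "y")
        assert not out["monotone"]

    def test_constant_outcome(self):
        df = pd.DataFrame({"x": np.arange(100.0), "y": np.ones(100)})
        out = linearity_check(df, "x", "y")
        assert out["estimates"] == [0.0, 0.0, 0.0, 0.0]


class TestMedialSensitivity:
    def test_no_subset_errors_with_counts(self):
        df = generate_cohort(CohortSpec(n=200, seed=6)).copy()
        df["jsn_lateral_base"] = 3
        df["jsn_medial_base"] = 0
        with pytest.raises(ValueError, match="n = 0"):
            medial_sensitivity(df)

    def test_bookkeeping_identity(self):
        df = generate_cohort(CohortSpec(n=375, seed=7))
        res = medial_sensitivity(df)
        d = res.diagnostics
        assert d["rows_in"] == d["subset_n"]
        assert d["rows_analyzed"] == d["subset_n"] - d["rows_grade3_excluded"] \
            - d["rows_missing"]

    def test_planted_medial_contrast(self):
        """A medial-only class effect shows up in the medial subset and
        not in the lateral complement."""
        hits = 0
        comp_null = 0
        n_rep = 12
        for s in range(n_rep):
            df = generate_cohort(CohortSpec(
                n=375, seed=4000 + s, or_progression=1.0,
                medial_class_or=(3.07, 1.62)))
            res = medial_sensitivity(df)
            hits += res.overall_p < 0.05
            lat = df[df["jsn_medial_base"] < df["jsn_lateral_base"]]
            sub = add_jsn_outcomes(lat)
            comp_null += (sub["jsn_progression"].mean()
                          <= df[df["jsn_medial_base"]
                                >= df["jsn_lateral_base"]]
                          ["jsn_progression"].mean() + 0.1)
        assert hits >= 0.8 * n_rep
        assert comp_null >= 0.8 * n_rep
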