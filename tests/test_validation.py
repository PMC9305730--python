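"""Class profiling, covariate standardisation, imputation, the multinomial
logit and Rubin pooling."""

import numpy as np
import pandas as pd
import pytest

from qolclasses.covariates import (
    CovariateTable,
    profile_classes,
    standardise_covariates,
)
from qolclasses.errors import ConfigError, RankDeficiencyError, UndefinedStatisticError
from qolclasses.imputation import impute_covariates
from qolclasses.regression import (
    build_design,
    fit_multinomial,
    pool_rubin,
    predict_proba,
    rrr_report,
)


def toy_table(n=8, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "age": rng.uniform(12, 25, n),
            "phq9": rng.integers(0, 28, n).astype(float),
            "female": rng.integers(0, 2, n).astype(float),
            "diagnosis": rng.choice(["other", "anxiety"], n),
        }
    )
    return CovariateTable(
        df, continuous=("age", "phq9"), binary=("female",),
        categorical={"diagnosis": ("other", "anxiety")},
    )


class TestProfileClasses:
    def test_single_class_equals_whole_cohort_summary(self):
        table = toy_table(40)
        prof = profile_classes(np.ones(40, dtype=int), table)
        assert prof.continuous.loc[("age", "median"), "class_1"] == pytest.approx(
            table.data["age"].median()
        )
        assert prof.categorical.loc[("female", 1, "pct"), "class_1"] == pytest.approx(
            100 * table.data["female"].mean()
        )

    def test_four_row_toy_medians_match_hand_calculation(self):
        df = pd.DataFrame(
            {"age": [14.0, 16.0, 20.0, 24.0], "phq9": [5.0, 7.0, 11.0, 27.0]}
        )
        table = CovariateTable(df, continuous=("age", "phq9"))
        prof = profile_classes(np.array([1, 1, 2, 2]), table)
        assert prof.continuous.loc[("age", "median"), "class_1"] == 15.0
        assert prof.continuous.loc[("phq9", "median"), "class_2"] == 19.0
        assert prof.continuous.loc[("age", "q1"), "class_1"] == 14.5

    def test_empty_class_yields_zero_counts(self):
        table = toy_table(6)
        labels = np.array([1, 1, 1, 1, 1, 3])
        prof = profile_classes(labels, table)
        assert prof.class_sizes.tolist() == [5, 1]

    def test_siqjr_medians_by_class_on_paper_cohort(self, paper_cohort):
        from qolclasses.lca import classify_modal

        labels = classify_modal(paper_cohort["fit"].posteriors)
        prof = profile_classes(
            labels,
            paper_cohort["covariates_cc"],
            utility=paper_cohort["scores"].utility.to_numpy(),
            class_names=paper_cohort["fit"].class_names,
        )
        med = prof.continuous.loc[("siq_jr", "median")]
        assert med["severe"] > med["no_mild"] + 20


class TestStandardise:
    def test_unit_sd_after_standardisation(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"phq9": np.clip(rng.normal(12, 6.6, 3000), 0, 27)})
        table = CovariateTable(df, continuous=("phq9",))
        out = standardise_covariates(table, variables=("phq9",))
        assert out.data["phq9"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        mean, sd = out.standardisation["phq9"]
        assert sd == pytest.approx(df["phq9"].std(ddof=1))

    def test_fixed_external_sd_is_used(self):
        df = pd.DataFrame({"phq9": [0.0, 6.6, 13.2]})
        table = CovariateTable(df, continuous=("phq9",))
        out = standardise_covariates(
            table, variables=("phq9",), sds={"phq9": 6.6}, means={"phq9": 6.6}
        )
        assert out.data["phq9"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_idempotent(self):
        table = toy_table(30)
        once = standardise_covariates(table, variables=("phq9",))
        twice = standardise_covariates(once, variables=("phq9",))
        assert np.allclose(once.data["phq9"], twice.data["phq9"], atol=1e-12)

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"phq9": [5.0] * 4})
        table = CovariateTable(df, continuous=("phq9",))
        with pytest.raises(UndefinedStatisticError):
            standardise_covariates(table, variables=("phq9",))


class TestImputation:
    def test_no_missing_data_gives_identical_copies(self):
        table = toy_table(25)
        imps = impute_covariates(table, m=3, seed=0)
        assert imps.m == 3
        for t in imps.tables:
            assert t.data[list(table.variables)].equals(
                imps.tables[0].data[list(table.variables)]
            )

    def test_same_seed_identical_imputations(self):
        table = toy_table(60, seed=2)
        table.data.loc[:5, "phq9"] = np.nan
        a = impute_covariates(table, m=2, seed=7)
        b = impute_covariates(table, m=2, seed=7)
        for ta, tb in zip(a.tables, b.tables):
            assert ta.data["phq9"].equals(tb.data["phq9"])

    def test_non_missing_cells_identical_across_copies(self):
        table = toy_table(60, seed=3)
        miss = table.data.sample(6, random_state=0).index
        table.data.loc[miss, "diagnosis"] = np.nan
        imps = impute_covariates(table, m=3, seed=1)
        keep = ~table.data["diagnosis"].isna()
        for t in imps.tables:
            assert (t.data.loc[keep, "diagnosis"] == table.data.loc[keep, "diagnosis"]).all()
            assert not t.data["diagnosis"].isna().any()

    def test_mcar_pooled_mean_close_to_complete_data_mean(self):
        rng = np.random.default_rng(4)
        n = 1500
        z = rng.normal(size=n)
        df = pd.DataFrame(
            {
                "age": 18 + 2 * z + rng.normal(0, 1, n),
                "phq9": np.clip(np.round(12 + 5 * z + rng.normal(0, 2, n)), 0, 27),
            }
        )
        full_mean = df["phq9"].mean()
        table = CovariateTable(df, continuous=("age", "phq9"))
        holes = rng.choice(n, size=n // 10, replace=False)
        table.data.loc[holes, "phq9"] = np.nan
        imps = impute_covariates(table, m=5, seed=2, n_iterations=5)
        pooled = np.mean([t.data["phq9"].mean() for t in imps.tables])
        se = df["phq9"].std() / np.sqrt(n)
        assert abs(pooled - full_mean) < 3 * se

    def test_entirely_missing_variable_rejected(self):
        table = toy_table(10)
        table.data["phq9"] = np.nan
        from qolclasses.errors import EmptyDataError

        with pytest.raises(EmptyDataError):
            impute_covariates(table, m=2, seed=0)


class TestFitMultinomial:
    def test_two_by_two_closed_form_odds_ratio(self):
        # exposed/unexposed x class counts [[40, 10], [20, 30]]
        x = np.array([1.0] * 50 + [0.0] * 50)
        labels = np.array([2] * 40 + [1] * 10 + [2] * 20 + [1] * 30)
        design = pd.DataFrame({"intercept": np.ones(100), "exposed": x})
        fit = fit_multinomial(labels, design, reference=1)
        assert np.exp(fit.coef[0, 1]) == pytest.approx(
            (40 * 30) / (10 * 20), abs=1e-6
        )

    def test_independent_covariate_has_null_rrr(self):
        rng = np.random.default_rng(5)
        n = 5000
        labels = rng.integers(1, 4, size=n)
        design = pd.DataFrame(
            {"intercept": np.ones(n), "x": rng.normal(size=n)}
        )
        fit = fit_multinomial(labels, design, reference=1)
        assert np.all(np.exp(fit.coef[:, 1]) > 0.9)
        assert np.all(np.exp(fit.coef[:, 1]) < 1.1)

    def test_matches_statsmodels_mnlogit(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(6)
        n = 800
        x = rng.normal(size=(n, 2))
        eta = np.column_stack([np.zeros(n), 0.8 * x[:, 0], -0.5 * x[:, 1] + 0.3 * x[:, 0]])
        p = np.exp(eta) / np.exp(eta).sum(axis=1, keepdims=True)
        labels = np.array([rng.choice(3, p=row) for row in p]) + 1
        design = pd.DataFrame(
            {"intercept": np.ones(n), "x1": x[:, 0], "x2": x[:, 1]}
        )
        ours = fit_multinomial(labels, design, reference=1)
        ref = sm.MNLogit(pd.Categorical(labels), design.to_numpy()).fit(disp=0)
        assert np.allclose(ours.coef, np.asarray(ref.params).T, atol=1e-5)
        assert np.allclose(
            np.sqrt(ours.variance_vector()),
            np.asarray(ref.bse).T.ravel(),
            rtol=1e-4,
        )

    def test_rank_deficiency_names_aliased_column(self):
        n = 50
        rng = np.random.default_rng(7)
        x = rng.normal(size=n)
        design = pd.DataFrame(
            {"intercept": np.ones(n), "x": x, "x_copy": x}
        )
        labels = rng.integers(1, 3, size=n)
        with pytest.raises(RankDeficiencyError, match="x"):
            fit_multinomial(labels, design, reference=1)

    def test_separation_triggers_ridge_fallback(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        labels = np.r_[np.ones(20), np.full(20, 2)].astype(int)
        design = pd.DataFrame({"intercept": np.ones(40), "x": x})
        with pytest.warns(RuntimeWarning, match="separation"):
            fit = fit_multinomial(labels, design, reference=1)
        assert fit.ridge > 0
        assert np.isfinite(fit.coef).all()


class TestPoolRubin:
    def test_identical_fits_reduce_to_single_fit_variance(self):
        est = [np.array([1.0, -0.5])] * 4
        var = [np.array([0.2, 0.1])] * 4
        pooled = pool_rubin(est, var)
        assert np.allclose(pooled.total_variance, [0.2, 0.1])
        assert np.all(np.isinf(pooled.df))

    def test_worked_arithmetic_example(self):
        pooled = pool_rubin(
            [np.array([1.0]), np.array([3.0])],
            [np.array([1.0]), np.array([1.0])],
        )
        assert pooled.estimate[0] == pytest.approx(2.0)
        assert pooled.between[0] == pytest.approx(2.0)
        assert pooled.total_variance[0] == pytest.approx(1.0 + 1.5 * 2.0)

    def test_ci_ordering_preserved_after_exponentiation(self):
        from qolclasses.regression import _ci

        pooled = pool_rubin(
            [np.array([0.5]), np.array([0.7])],
            [np.array([0.04]), np.array([0.05])],
        )
        lo, hi = _ci(pooled)
        assert np.exp(lo[0]) < np.exp(pooled.estimate[0]) < np.exp(hi[0])

    def test_non_conformable_fits_rejected(self):
        with pytest.raises(ConfigError):
            pool_rubin([np.zeros(2), np.zeros(3)], [np.ones(2), np.ones(3)])


class TestRRRReport:
    def test_null_model_accuracy_equals_largest_class_share(self):
        rng = np.random.default_rng(8)
        n = 400
        labels = rng.choice([1, 2, 3], p=[0.5, 0.3, 0.2], size=n)
        df = pd.DataFrame({"age": rng.normal(18, 2, n)})
        table = CovariateTable(df, continuous=("age",))
        # age carries no signal; intercept-only behaviour
        design = build_design(table, ())
        fit = fit_multinomial(labels, design, reference=1)
        prob = predict_proba(fit, design)
        modal = np.array(fit.classes)[prob.argmax(axis=1)]
        assert (modal == labels).mean() == pytest.approx(
            max(np.bincount(labels)[1:]) / n
        )

    def test_symptom_model_improves_accuracy_when_symptoms_matter(self):
        rng = np.random.default_rng(9)
        n = 1200
        cls = rng.integers(1, 4, size=n)
        phq = np.clip(np.round(rng.normal(5 + 6 * (cls - 1), 4)), 0, 27)
        df = pd.DataFrame(
            {
                "age": rng.normal(18, 2, n),
                "female": rng.integers(0, 2, n).astype(float),
                "lgbtiq": rng.integers(0, 2, n).astype(float),
                "neet": rng.integers(0, 2, n).astype(float),
                "phq9": phq,
                "gad7": np.clip(np.round(rng.normal(4 + 4 * (cls - 1), 4)), 0, 21),
                "siq_jr": np.clip(np.round(rng.normal(5 + 12 * (cls - 1), 12)), 0, 90),
                "psqi": np.clip(np.round(rng.normal(7 + 2 * (cls - 1), 3)), 0, 21),
                "region": rng.choice(["metropolitan", "regional"], n),
                "diagnosis": rng.choice(["other", "anxiety"], n),
                "clinical_stage": rng.choice(["0-1a", "1b", "2-4"], n),
            }
        )
        df.loc[rng.choice(n, 30, replace=False), "phq9"] = np.nan
        table = CovariateTable(
            df,
            continuous=("age", "phq9", "gad7", "siq_jr", "psqi"),
            binary=("female", "lgbtiq", "neet"),
            categorical={
                "region": ("metropolitan", "regional"),
                "diagnosis": ("other", "anxiety"),
                "clinical_stage": ("0-1a", "1b", "2-4"),
            },
        )
        imps = impute_covariates(table, m=3, seed=3, n_iterations=3)
        report = rrr_report(cls, imps, reference_class=1)
        assert report.accuracy["model2"] >= report.accuracy["model1"]
        t2 = report.tables["model2"]
        assert ((t2["ci_low"] <= t2["rrr"]) & (t2["rrr"] <= t2["ci_high"])).all()
        assert (t2["rrr"] > 0).all()

    def test_rrr_recovery_from_known_multinomial_logit(self):
        # class membership generated directly from a known 2-class logit
        rng = np.random.default_rng(10)
        n = 3000
        x = rng.normal(size=n)
        beta = 0.9
        p2 = 1 / (1 + np.exp(-(-0.3 + beta * x)))
        labels = 1 + (rng.random(n) < p2)
        design = pd.DataFrame({"intercept": np.ones(n), "x": x})
        fit = fit_multinomial(labels, design, reference=1)
        se = np.sqrt(fit.variance_vector()[1])
        assert abs(fit.coef[0, 1] - beta) < 3 * se
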