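import numpy as np
import pandas as pd
import pytest

from pgxoutcomes.association import (
    BinaryOutcomeModel,
    DurationModel,
    export_forest,
    fit_binary,
    fit_duration,
    run_all,
)


def toy_table(n=400, seed=0, p_case=0.3, phenos=("normal", "poor")):
    rng = np.random.default_rng(seed)
    pheno = rng.choice(phenos, size=n)
    return pd.DataFrame(
        {
            "person_id": [f"p{i}" for i in range(n)],
            "ssri": "ssri_citalopram",
            "phenotype": pheno,
            "activity_score": np.where(pheno == "poor", 0.0, 2.0),
            "switch_60": rng.choice(["case", "control"], size=n, p=[p_case, 1 - p_case]),
            "duration_count": rng.integers(1, 40, size=n),
            "duration_weeks": rng.uniform(0, 200, size=n),
            "age_at_first_rx": rng.integers(40, 70, size=n),
            "sex": rng.integers(0, 2, size=n),
            "batch": rng.choice(["b1", "b2"], size=n),
            "antipsychotic_overlap": rng.random(size=n) < 0.05,
            "broad_depression": rng.random(size=n) < 0.8,
        }
    )


class TestFitBinary:
    def test_estimate_matches_unadjusted_log_odds_ratio(self):
        """With no covariates the logistic coefficient is the log of the
        2x2-table odds ratio."""
        df = toy_table(n=2000, seed=1)
        res = [
            r
            for r in fit_binary(df, "switch_60", covariates=())
            if r.term == "poor vs normal"
        ][0]
        tab = pd.crosstab(df["phenotype"], df["switch_60"])
        manual = np.log(
            (tab.loc["poor", "case"] * tab.loc["normal", "control"])
            / (tab.loc["poor", "control"] * tab.loc["normal", "case"])
        )
        assert res.estimate == pytest.approx(manual, abs=1e-6)
        assert res.or_ == pytest.approx(np.exp(res.estimate))
        assert res.ci_low < res.estimate < res.ci_high

    def test_zero_cases_flagged_inestimable(self):
        df = toy_table(n=50, seed=2)
        df["switch_60"] = "control"
        res = fit_binary(df, "switch_60")
        assert all(np.isnan(r.estimate) for r in res)
        assert all(r.flags == "no_cases" for r in res)

    def test_complete_separation_flagged(self):
        df = toy_table(n=6, seed=3)
        df["phenotype"] = ["poor"] * 3 + ["normal"] * 3
        df["switch_60"] = ["case"] * 3 + ["control"] * 3
        res = [
            r
            for r in fit_binary(df, "switch_60", covariates=())
            if r.term == "poor vs normal"
        ][0]
        assert res.flags != ""

    def test_numeric_status_encoding_accepted(self):
        df = toy_table(n=300, seed=4)
        num = df.assign(switch_60=df["switch_60"].map({"case": 1.0, "control": 0.0}))
        a = fit_binary(df, "switch_60", covariates=())[0]
        b = fit_binary(num, "switch_60", covariates=())[0]
        assert a.estimate == pytest.approx(b.estimate)

    def test_excluded_rows_dropped(self):
        df = toy_table(n=300, seed=5)
        df.loc[:49, "switch_60"] = "excluded"
        res = fit_binary(df, "switch_60", covariates=())[0]
        assert res.n_cases + res.n_controls == 250


class TestFitDuration:
    def test_covariate_free_fit_equals_group_mean_difference(self):
        df = toy_table(n=500, seed=6)
        res = [
            r
            for r in fit_duration(df, "count", covariates=())
            if r.term == "poor vs normal"
        ][0]
        y = np.log(df["duration_count"] + 1.0)
        manual = y[df["phenotype"] == "poor"].mean() - y[df["phenotype"] == "normal"].mean()
        assert res.estimate == pytest.approx(manual, abs=1e-9)

    def test_zero_variance_flagged(self):
        df = toy_table(n=50, seed=7)
        df["duration_count"] = 5
        res = fit_duration(df, "count")
        assert all(r.flags == "zero_variance" for r in res)

    def test_activity_mode_slope(self):
        rng = np.random.default_rng(8)
        df = toy_table(n=3000, seed=8)
        df["duration_count"] = np.exp(
            1.5 + 0.2 * df["activity_score"] + rng.normal(0, 0.3, len(df))
        ).round().clip(1)
        res = fit_duration(df, "count", predictor_mode="activity_score", covariates=())[0]
        assert res.term == "activity_score"
        assert res.estimate == pytest.approx(0.2, abs=0.05)


@pytest.fixture(scope="module")
def table():
    df = toy_table(n=600, seed=9)
    for col in ("switch_30", "switch_90", "disc_def1", "disc_def2",
                "side_effect_30", "side_effect_60"):
        df[col] = df["switch_60"]
    # three SSRIs to exercise the full grid
    df["ssri"] = np.tile(
        ["ssri_citalopram", "ssri_escitalopram", "ssri_sertraline"], 200
    )
    return df


class TestRunAll:

    def test_combinatorial_coverage(self, table):
        res = run_all(table)
        for mode in ("phenotype_categorical", "activity_score"):
            sub = res[res["predictor"] == mode]
            assert sub.groupby(["ssri", "outcome"]).ngroups == 27

    def test_raw_p_kept_alongside_bonferroni_flag(self, table):
        res = run_all(table)
        assert {"p", "bonferroni_significant"} <= set(res.columns)
        assert ((res["p"] >= 0.05 / 4) & res["bonferroni_significant"]).sum() == 0

    def test_deterministic(self, table):
        a = run_all(table).to_csv(index=False)
        b = run_all(table).to_csv(index=False)
        assert a == b

    def test_subgroup_filters_rows(self, table):
        full = [r for r in fit_binary(table, "switch_60", ssri="ssri_citalopram")]
        sub = [
            r
            for r in fit_binary(
                table, "switch_60", ssri="ssri_citalopram", subgroup="broad_depression"
            )
        ]
        assert sub[0].n_cases + sub[0].n_controls < full[0].n_cases + full[0].n_controls


class TestForest:
    def test_or_columns_are_exp_of_estimates(self):
        df = toy_table(n=400, seed=10)
        res = run_all(df, predictor_modes=("phenotype_categorical",))
        forest = export_forest(res)
        binary = res[~res["outcome"].isin(["duration_count", "duration_weeks"])]
        assert len(forest) == len(binary)
        np.testing.assert_allclose(
            forest["or"].to_numpy(), np.exp(binary["estimate"]).to_numpy()
        )

    def test_inestimable_rows_have_missing_markers(self):
        df = toy_table(n=60, seed=11)
        df["switch_60"] = "control"
        res = run_all(df, predictor_modes=("phenotype_categorical",))
        forest = export_forest(res)
        assert forest.loc[forest["outcome"] == "switch_60", "or"].isna().all()


class TestEstimatorInterface:
    def test_fit_sets_results_and_params_round_trip(self):
        df = toy_table(n=300, seed=12)
        model = BinaryOutcomeModel(outcome="switch_60", covariates=())
        assert model.get_params()["outcome"] == "switch_60"
        model.fit(df)
        assert len(model.results_) >= 1
        assert model.get_results()["outcome"].iloc[0] == "switch_60"

    def test_set_params_sklearn_style(self):
        model = DurationModel().set_params(definition="weeks")
        assert model.definition == "weeks"
        df = toy_table(n=300, seed=13)
        model.covariates = ()
        model.fit(df)
        assert model.results_[0].outcome == "duration_weeks"
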