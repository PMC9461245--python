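"""Cell-level estimator: logit fit, counterfactual prediction, D index."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import iop_lifecycle as il
from iop_lifecycle.exceptions import CellDegenerate, RankDeficientDesign
from iop_lifecycle.iop import empirical_type_means


class TestFitLogit:
    def test_saturated_2x2_closed_form(self, saturated_2x2):
        fit = il.fit_logit(saturated_2x2, "y", ["x"])
        assert fit.beta["x"] == pytest.approx(np.log(9), abs=1e-6)
        assert fit.alpha == pytest.approx(np.log(1 / 3), abs=1e-6)
        assert fit.converged and not fit.separation_flag
        assert fit.n == 16

    def test_independent_balanced_table_gives_zero_slope(self):
        # y ⟂ x, perfectly balanced: symmetry forces beta = 0
        df = pd.DataFrame({"x": [0, 0, 1, 1], "y": [0, 1, 0, 1]})
        fit = il.fit_logit(df, "y", ["x"])
        assert fit.beta["x"] == pytest.approx(0.0, abs=1e-8)

    def test_all_case_and_all_noncase_rejected(self):
        df = pd.DataFrame({"x": [0, 1, 0, 1], "y": [1, 1, 1, 1]})
        with pytest.raises(CellDegenerate):
            il.fit_logit(df, "y", ["x"])
        df["y"] = 0
        with pytest.raises(CellDegenerate):
            il.fit_logit(df, "y", ["x"])

    def test_constant_column_dropped_and_logged(self, saturated_2x2):
        df = saturated_2x2.assign(z=1)
        fit = il.fit_logit(df, "y", ["x", "z"])
        assert fit.dropped_columns == ["z"]
        assert list(fit.beta.index) == ["x"]

    def test_collinear_columns_named(self, saturated_2x2):
        df = saturated_2x2.assign(x2=lambda d: 1 - d["x"])
        with pytest.raises(RankDeficientDesign) as exc:
            il.fit_logit(df, "y", ["x", "x2"])
        assert "x2" in exc.value.columns

    def test_separation_flagged(self):
        rng = np.random.default_rng(0)
        x = np.repeat([0, 1], 30)
        df = pd.DataFrame({"x": x, "y": x, "z": rng.integers(0, 2, 60)})
        fit = il.fit_logit(df, "y", ["x", "z"])
        assert fit.separation_flag

    def test_parameter_recovery_single_age_process(self):
        """Generator with one grid age is exactly a logit; recover each beta
        within 3 standard errors at n = 10^4."""
        cfg = il.default_config(
            n_per_cell=10_000, countries=("A",), cohort_bounds=((1950, 1955),),
            age_grid=(50,), seed=17,
        )
        coded, _ = il.code_panel(il.generate_panel(cfg))
        coded[["outcome_any", "outcome_ge_median"]] = il.build_outcomes(coded, 50)
        fit = il.fit_logit(coded, "outcome_any", il.CIRCUMSTANCES)
        for name in il.CIRCUMSTANCES:
            truth = cfg.effect_profile[name].at(50, cfg.age_ref)
            assert abs(fit.beta[name] - truth) < 3 * fit.bse[name], name


class TestPredictCounterfactual:
    def test_zero_linpred_gives_half(self):
        fit = il.LogitFit(alpha=0.0, beta=pd.Series({"x": 2.0}),
                          bse=pd.Series({"x": np.nan}), n=4,
                          converged=True, separation_flag=False)
        df = pd.DataFrame({"x": [0.0]})
        assert il.predict_counterfactual(fit, df)[0] == pytest.approx(0.5)

    def test_plugin_from_saturated_fit(self, saturated_2x2):
        fit = il.fit_logit(saturated_2x2, "y", ["x"])
        yhat = il.predict_counterfactual(fit, saturated_2x2)
        assert yhat[saturated_2x2["x"] == 1] == pytest.approx(0.75, abs=1e-6)
        assert yhat[saturated_2x2["x"] == 0] == pytest.approx(0.25, abs=1e-6)

    def test_permutation_equivariance(self, saturated_2x2):
        fit = il.fit_logit(saturated_2x2, "y", ["x"])
        perm = saturated_2x2.sample(frac=1, random_state=1)
        np.testing.assert_allclose(
            il.predict_counterfactual(fit, perm),
            il.predict_counterfactual(fit, saturated_2x2)[perm.index.to_numpy()],
        )

    def test_missing_columns_rejected(self, saturated_2x2):
        fit = il.fit_logit(saturated_2x2, "y", ["x"])
        with pytest.raises(KeyError):
            il.predict_counterfactual(fit, pd.DataFrame({"w": [1.0]}))


class TestDissimilarityIndex:
    @pytest.mark.parametrize(
        "yhat, expected",
        [
            ([0.5, 0.5], 0.0),     # even opportunities -> 0
            ([1.0, 0.0], 0.5),     # direct evaluation of the estimator
            ([0.8, 0.2], 0.3),
        ],
    )
    def test_worked_examples(self, yhat, expected):
        assert il.dissimilarity_index(yhat) == pytest.approx(expected, abs=1e-12)

    def test_replication_and_permutation_invariance(self):
        yhat = np.array([0.9, 0.1, 0.4, 0.4, 0.7])
        d = il.dissimilarity_index(yhat)
        assert il.dissimilarity_index(np.tile(yhat, 3)) == pytest.approx(d)
        rng = np.random.default_rng(3)
        assert il.dissimilarity_index(rng.permutation(yhat)) == pytest.approx(d)

    def test_zero_mean_undefined(self):
        with pytest.raises(CellDegenerate):
            il.dissimilarity_index([0.0, 0.0, 0.0])

    def test_weight_validation(self):
        with pytest.raises(ValueError):
            il.dissimilarity_index([0.5, 0.5], weights=[0.9, 0.9])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=60).filter(lambda v: sum(v) > 0))
    def test_bounds_property(self, yhat):
        assert 0.0 <= il.dissimilarity_index(yhat) <= 1.0

    def test_type_level_oracle_equivalence(self, saturated_2x2):
        """Individual-level D with uniform weights equals type-level D with
        type population shares, because predictions are constant within
        types."""
        df = saturated_2x2.assign(w=[0, 1] * 8)
        fit = il.fit_logit(df, "y", ["x", "w"])
        yhat = il.predict_counterfactual(fit, df)
        d_ind = il.dissimilarity_index(yhat)

        types = pd.DataFrame({"x": df["x"], "w": df["w"], "yhat": yhat})
        grouped = types.groupby(["x", "w"])["yhat"].agg(["first", "size"])
        d_type = il.dissimilarity_index(
            grouped["first"].to_numpy(),
            (grouped["size"] / grouped["size"].sum()).to_numpy(),
        )
        assert abs(d_ind - d_type) < 1e-12


class TestEstimateCell:
    def test_composition_and_invariants(self, coded_cell):
        res = il.estimate_cell(coded_cell, "outcome_any", il.CIRCUMSTANCES)
        assert res.ybar == pytest.approx(float(np.mean(res.yhat)), abs=1e-12)
        assert 0.0 <= res.d_index <= 1.0
        assert res.reliable and res.reasons == []
        assert np.allclose(res.weights, 1.0 / res.n)

    def test_duplicated_records_same_d(self, coded_cell):
        res = il.estimate_cell(coded_cell, "outcome_any", il.CIRCUMSTANCES)
        doubled = pd.concat([coded_cell, coded_cell], ignore_index=True)
        res2 = il.estimate_cell(doubled, "outcome_any", il.CIRCUMSTANCES)
        assert res2.d_index == pytest.approx(res.d_index, abs=1e-10)

    def test_small_cell_flagged_unreliable(self, coded_cell):
        small = coded_cell.iloc[:40]
        res = il.estimate_cell(small, "outcome_any", il.CIRCUMSTANCES)
        assert not res.reliable
        assert any(reason.startswith("n=") for reason in res.reasons)

    def test_summary_mentions_key_quantities(self, coded_cell):
        res = il.estimate_cell(coded_cell, "outcome_any", il.CIRCUMSTANCES)
        text = res.summary()
        assert "D index" in text and "harm" in text

    def test_lower_bound_adding_circumstance(self):
        """Adding an informative circumstance (weakly) raises D: the index is
        a lower bound that grows with the observed circumstance set."""
        diffs = []
        for seed in range(20):
            cfg = il.default_config(
                n_per_cell=2000, countries=("A",),
                cohort_bounds=((1950, 1955),), age_grid=(55,), seed=seed,
            )
            coded, _ = il.code_panel(il.generate_panel(cfg))
            coded[["outcome_any", "outcome_ge_median"]] = (
                il.build_outcomes(coded, 55))
            d_small = il.estimate_cell(
                coded, "outcome_any", ["financial_hardship"]).d_index
            d_large = il.estimate_cell(
                coded, "outcome_any", ["financial_hardship", "harm"]).d_index
            diffs.append(d_large - d_small)
        # one-sided: mean increase positive beyond Monte-Carlo noise
        diffs = np.array(diffs)
        assert diffs.mean() > 0
        assert diffs.mean() / (diffs.std(ddof=1) / np.sqrt(len(diffs))) > 2


class TestEmpiricalTypeMeans:
    def test_matches_groupby_means(self, saturated_2x2):
        yhat = empirical_type_means(saturated_2x2, ["x"], "y")
        assert set(np.round(yhat, 6)) == {0.25, 0.75}

    def test_no_columns_gives_grand_mean(self, saturated_2x2):
        yhat = empirical_type_means(saturated_2x2, [], "y")
        assert np.allclose(yhat, saturated_2x2["y"].mean())
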