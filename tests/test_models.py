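"""Cross-sectional and random-intercept association models."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from coda24 import (
    CohortParams,
    CompositionalLinearModel,
    CompositionalMixedModel,
    IlrTransformer,
    OutcomeModel,
    Rotation,
    composition_test,
    fit_cross_sectional,
    fit_longitudinal,
    influence_exclude_refit,
    rotation_table,
    simulate_cohort,
)
from coda24.composition import ilr_array
from coda24.models import (
    RankDeficientDesign,
    cohen_label,
    select_cross_sectional,
)


class TestRecordSelection:
    def test_first_timepoint_preferred_second_as_fallback(self):
        records = pd.DataFrame(
            {
                "child_id": ["a", "a", "b"],
                "timepoint": [1, 2, 2],
                "age_months": [10.0, 19.0, 30.0],
                "sex": [0, 0, 1],
                "pa_min": [220.0] * 3,
                "sb_min": [400.0] * 3,
                "sleep_min": [820.0] * 3,
                "gm_raw": [40.0, 50.0, 55.0],
            }
        )
        sel = select_cross_sectional(records, "gm_raw")
        assert sel.set_index("child_id")["timepoint"].to_dict() == {"a": 1, "b": 2}

    def test_incomplete_first_timepoint_falls_through(self):
        records = pd.DataFrame(
            {
                "child_id": ["a", "a"],
                "timepoint": [1, 2],
                "age_months": [10.0, 19.0],
                "sex": [0, 0],
                "pa_min": [220.0] * 2,
                "sb_min": [400.0] * 2,
                "sleep_min": [820.0] * 2,
                "gm_raw": [np.nan, 50.0],
            }
        )
        sel = select_cross_sectional(records, "gm_raw")
        assert sel["timepoint"].tolist() == [2]


class TestLinearModel:
    def test_noiseless_coefficients_recovered(self, noiseless_records):
        fit = fit_cross_sectional(noiseless_records, "gm_raw", Rotation.SLEEP)
        assert fit.params["intercept"] == pytest.approx(27.0, abs=1e-8)
        assert fit.params["ilr1"] == pytest.approx(8.5, abs=1e-8)
        assert fit.params["ilr2"] == pytest.approx(6.0, abs=1e-8)
        assert fit.params["age_months"] == pytest.approx(1.1, abs=1e-8)
        assert fit.params["sex"] == pytest.approx(0.5, abs=1e-8)

    def test_rotation_invariant_fit_statistics(self, default_records):
        fits = {r: fit_cross_sectional(default_records, "gm_raw", r) for r in Rotation}
        lls = [f.llf for f in fits.values()]
        r2s = [f.rsquared for f in fits.values()]
        assert max(lls) - min(lls) < 1e-8
        assert max(r2s) - min(r2s) < 1e-8
        resid = [f.resid for f in fits.values()]
        assert np.max(np.abs(resid[0] - resid[1])) < 1e-8

    def test_minimum_sample_enforced(self, default_records):
        with pytest.raises(ValueError, match="at least"):
            fit_cross_sectional(default_records.head(8), "gm_raw", min_records=10)

    def test_constant_sex_column_raises(self, default_records):
        boys = default_records[default_records["sex"] == 0]
        with pytest.raises(RankDeficientDesign, match="sex"):
            fit_cross_sectional(boys, "gm_raw")

    def test_sklearn_protocol(self, default_records):
        sel = select_cross_sectional(default_records, "gm_raw")
        est = CompositionalLinearModel(rotation="SB")
        assert est.get_params()["rotation"] == "SB"
        est.fit(sel, sel["gm_raw"].to_numpy())
        pred = est.predict(sel)
        assert pred == pytest.approx(est.fit_.fittedvalues)
        cloned = est.set_params(rotation="PA")
        assert cloned.get_params()["rotation"] == "PA"


class TestMixedModel:
    def test_zero_random_intercept_collapses_to_ols(self):
        params = CohortParams(
            n_children=120,
            dropout_prob=0.0,
            outcomes={"gm_raw": OutcomeModel(27.0, 8.5, 6.0, 1.1, 0.5, tau=0.0, sigma=3.0)},
        )
        records = simulate_cohort(params, seed=0).records
        mixed = fit_longitudinal(records, "gm_raw", Rotation.SLEEP)
        # the ML estimate sits at the boundary here, so the mixed fit
        # collapses onto the pooled OLS fit
        assert mixed.tau2 == pytest.approx(0.0, abs=1e-6)
        ols = sm.OLS(mixed.y, mixed.design).fit()
        assert mixed.params.to_numpy() == pytest.approx(ols.params, abs=1e-4)
        assert mixed.r2_marginal == pytest.approx(mixed.r2_conditional, abs=1e-6)

    def test_rotation_invariant_loglik(self, default_records):
        lls = [fit_longitudinal(default_records, "gm_raw", r).llf for r in Rotation]
        assert max(lls) - min(lls) < 1e-6

    def test_single_timepoint_children_warns_not_fails(self, default_records):
        singles = default_records[default_records["timepoint"] == 1]
        with pytest.warns(UserWarning, match="single record"):
            fit = fit_longitudinal(singles, "gm_raw")
        assert fit.tau2 >= 0

    def test_variance_partition_sane(self, default_records):
        fit = fit_longitudinal(default_records, "gm_raw")
        assert 0 <= fit.r2_marginal <= fit.r2_conditional <= 1


class TestCompositionTest:
    def test_partial_f_matches_statsmodels_oracle(self, default_records):
        full = fit_cross_sectional(default_records, "gm_raw")
        test = composition_test(full)
        # independent route: statsmodels' F test for dropping both ilr terms
        res_full = sm.OLS(full.y, full.design).fit()
        res_null = sm.OLS(full.y, full.design[:, [0, 3, 4]]).fit()
        oracle = res_full.compare_f_test(res_null)
        assert test.statistic == pytest.approx(oracle[0], rel=1e-10)
        assert test.pvalue == pytest.approx(oracle[1], rel=1e-10)
        assert test.df == (2.0, res_full.df_resid)

    def test_r2_delta_and_statistics_rotation_invariant(self, default_records):
        stats = []
        for rot in Rotation:
            cs = composition_test(fit_cross_sectional(default_records, "gm_raw", rot))
            lmm = composition_test(fit_longitudinal(default_records, "gm_raw", rot))
            stats.append((cs.statistic, cs.r2_delta, lmm.statistic, lmm.r2_delta))
        arr = np.array(stats)
        assert np.ptp(arr, axis=0) == pytest.approx([0, 0, 0, 0], abs=1e-6)

    def test_mixed_lrt_nonnegative_and_2df(self, default_records):
        t = composition_test(fit_longitudinal(default_records, "se_raw"))
        assert t.kind == "chi2" and t.df == 2
        assert t.statistic >= 0 and 0 <= t.pvalue <= 1

    def test_mismatched_null_rejected(self, default_records):
        full = fit_cross_sectional(default_records, "gm_raw")
        null_other = fit_cross_sectional(
            default_records.iloc[: len(default_records) // 2],
            "gm_raw",
            include_composition=False,
        )
        with pytest.raises(ValueError, match="same observations"):
            composition_test(full, null_other)

    @pytest.mark.parametrize(
        "r2d,label",
        [
            (0.01, "very small"),
            (0.02, "small"),
            (0.12, "small"),
            (0.130, "medium"),
            (0.26, "medium"),
            (0.30, "large"),
        ],
    )
    def test_cohen_bands_boundaries_upper_class(self, r2d, label):
        assert cohen_label(r2d) == label


class TestInfluenceExclusion:
    def test_planted_gross_outlier_always_excluded(self, default_records):
        records = select_cross_sectional(default_records, "gm_raw").copy()
        fit0 = fit_cross_sectional(records, "gm_raw")
        # plant a 10-sigma outcome shift at a high-leverage composition
        sigma = float(np.std(fit0.resid, ddof=1))
        idx = records.index[0]
        records.loc[idx, ["pa_min", "sb_min", "sleep_min"]] = [30.0, 610.0, 800.0]
        records.loc[idx, "gm_raw"] += 10 * sigma
        fit = fit_cross_sectional(records, "gm_raw")
        excluded, refit = influence_exclude_refit(fit, records, "gm_raw")
        assert idx in excluded
        assert refit.nobs == fit.nobs - len(excluded)

    def test_clean_data_few_exclusions(self, default_records):
        fit = fit_cross_sectional(default_records, "gm_raw")
        excluded, _ = influence_exclude_refit(fit, default_records, "gm_raw")
        assert len(excluded) <= 3

    def test_cooks_cutoff_is_4_over_n(self, default_records):
        # both criteria must hold; with an impossible residual bound nothing
        # can be excluded regardless of Cook's distance
        fit = fit_cross_sectional(default_records, "gm_raw")
        excluded, refit = influence_exclude_refit(
            fit, default_records, "gm_raw", resid_bound=np.inf
        )
        assert len(excluded) == 0 and refit is fit

    def test_mixed_model_diagnostics_available(self, default_records):
        from coda24.models import influence_diagnostics

        fit = fit_longitudinal(default_records, "gm_raw")
        diag = influence_diagnostics(fit)
        assert len(diag) == fit.nobs
        assert (diag["cooks_d"] >= 0).all()


class TestRotationTable:
    def test_three_rows_shared_loglik(self, default_records):
        table = rotation_table(default_records, "gm_raw")
        assert list(table["reference"]) == ["PA", "SB", "SLEEP"]
        assert table["llf"].max() - table["llf"].min() < 1e-8
        inside = (table["ci_low"] <= table["beta_ilr1"]) & (
            table["beta_ilr1"] <= table["ci_high"]
        )
        assert inside.all()

    def test_generator_effect_signs_recovered(self, default_records):
        # true gm_raw effect: positive on the sleep pivot, negative on SB
        table = rotation_table(default_records, "gm_raw").set_index("reference")
        assert table.loc["SLEEP", "beta_ilr1"] > 0
        assert table.loc["SB", "beta_ilr1"] < 0


def test_ilr_transformer_in_pipeline(default_records):
    from sklearn.pipeline import make_pipeline
    from sklearn.linear_model import LinearRegression

    sel = select_cross_sectional(default_records, "gm_raw")
    X = sel[["pa_min", "sb_min", "sleep_min"]]
    t = IlrTransformer(rotation="SLEEP").fit(X)
    z = t.transform(X)
    assert z == pytest.approx(ilr_array(X.to_numpy(dtype=float), Rotation.SLEEP))
    pipe = make_pipeline(IlrTransformer("SLEEP"), LinearRegression())
    pipe.fit(X, sel["gm_raw"])
    assert pipe.predict(X).shape == (len(sel),)
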