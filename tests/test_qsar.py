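"""Model enumeration, MLR fitting and the validation battery."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

from mlcqsar import errors
from mlcqsar.qsar import (
    ModelSpec,
    PAPER_GROUPS,
    QSARModel,
    ScreeningRules,
    enumerate_models,
    fit_mlr,
    screen_models,
)

from conftest import brute_force_loo_press


class TestEnumerateModels:
    def test_full_enumeration(self):
        specs = enumerate_models(PAPER_GROUPS)
        assert [s.label for s in specs] == [f"M{i}" for i in range(1, 13)]
        assert specs[:6] == [s for s in specs if s.response == "log_bb"]
        m5 = specs[4]
        assert m5.label == "M5"
        assert m5.response == "log_bb"
        assert m5.predictors == ("log_km_over_kam", "hba", "nrb", "parachor_P")

    def test_starred_variants_drop_flexibility(self):
        starred = enumerate_models(PAPER_GROUPS, include_flexibility="without")
        assert [s.label for s in starred] == ["M5*", "M11*", "M12*"]
        assert all("nrb" not in s.predictors for s in starred)
        assert starred[2].predictors == ("log_km_over_kam", "hba", "mw")

    def test_both_gives_fifteen(self):
        assert len(enumerate_models(PAPER_GROUPS, include_flexibility="both")) == 15

    def test_reduced_combinatorics(self):
        groups = {"I": ("tpsa", "hba"), "II": ("mw",), "III": ("nrb",)}
        specs = enumerate_models(groups, responses=("log_bb",))
        assert len(specs) == 2

    def test_malformed_grouping(self):
        with pytest.raises(errors.ValidationError):
            enumerate_models({"I": ("tpsa",), "II": ()})


class TestFit:
    def test_m5_coefficients_match_reported_equation(self, m5_results):
        got = np.round(
            [m5_results.params[k] for k in ("const", "log_km_over_kam", "hba", "nrb", "parachor_P")],
            3,
        )
        assert got.tolist() == [0.253, 0.198, -0.160, -0.019, 0.002]

    def test_m5_standard_errors_match_reported_equation(self, m5_results):
        got = np.round(
            [m5_results.bse[k] for k in ("const", "log_km_over_kam", "hba", "nrb", "parachor_P")],
            3,
        )
        assert got.tolist() == [0.232, 0.091, 0.023, 0.016, 0.000]

    def test_m12_star_hba_coefficient(self, table3):
        res = fit_mlr(ModelSpec("M12*", "log_bb_star", ("log_km_over_kam", "hba", "mw")), table3)
        assert round(res.params["hba"], 3) == -0.156

    def test_exact_linear_response_fits_perfectly(self, table3):
        t = table3.copy()
        t["y"] = 2.0 - 0.3 * t["hba"] + 0.01 * t["mw"]
        res = fit_mlr(ModelSpec("X", "y", ("hba", "mw")), t)
        assert res.rsquared == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(res.resid, 0.0, atol=1e-10)
        assert math.isinf(res.stats().fvalue)

    def test_residuals_sum_to_zero(self, m5_results):
        assert abs(res_sum := m5_results.resid.sum()) < 1e-10 * m5_results.nobs

    def test_rank_deficient_design(self, table3):
        t = table3.copy()
        t["mw_copy"] = t["mw"]
        with pytest.raises(errors.SingularFitError):
            QSARModel(ModelSpec("X", "log_bb", ("mw", "mw_copy")), t)

    def test_too_few_observations(self, table3):
        t = table3.iloc[:4]
        with pytest.raises(errors.ValidationError):
            QSARModel(ModelSpec("X", "log_bb", ("mw", "hba", "nrb", "tpsa")), t)

    def test_nesting_monotonicity(self, table3, m5_results):
        """Adding NRB to the starred model can only increase R^2."""
        starred = fit_mlr(
            ModelSpec("M5*", "log_bb", ("log_km_over_kam", "hba", "parachor_P")), table3
        )
        assert m5_results.rsquared >= starred.rsquared


class TestLooPress:
    def test_shortcut_equals_refit_oracle_on_m5(self, m5_results):
        X = m5_results.model.exog.to_numpy(float)
        y = m5_results.model.endog
        oracle = brute_force_loo_press(y, X)
        assert m5_results.press == pytest.approx(oracle, rel=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_shortcut_equals_refit_oracle_random_designs(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 20, 3
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
        y = rng.normal(size=n)
        t = pd.DataFrame(X[:, 1:], columns=["x1", "x2", "x3"])
        t["y"] = y
        res = fit_mlr(ModelSpec("R", "y", ("x1", "x2", "x3")), t)
        assert res.press == pytest.approx(brute_force_loo_press(y, X), rel=1e-10)

    def test_matches_statsmodels_press(self, m5_results):
        sm_press = sm.OLS(m5_results.model.endog, m5_results.model.exog).fit().get_influence().ess_press
        assert m5_results.press == pytest.approx(float(sm_press), rel=1e-10)

    def test_duplicated_rows_keep_press_finite(self, table3):
        twin = table3.assign(compound_id=[f"{c}b" for c in table3["compound_id"]])
        t = pd.concat([table3, twin], ignore_index=True)
        res = fit_mlr(ModelSpec("D", "log_bb", ("log_km_over_kam", "hba", "nrb", "parachor_P")), t)
        assert np.isfinite(res.press)
        assert res.press < 2.0 * res.ss_resid + 1e-9  # twinned points halve leverages

    def test_r2pred_identity(self, m5_results):
        assert m5_results.rsquared_pred == pytest.approx(
            1.0 - m5_results.press / m5_results.ss_total, abs=1e-14
        )


class TestVif:
    def test_orthogonal_predictors_have_unit_vif(self):
        n = 64
        rng = np.random.default_rng(3)
        # orthogonalize against the intercept too, so correlations are exactly 0
        q, _ = np.linalg.qr(np.column_stack([np.ones(n), rng.normal(size=(n, 3))]))
        t = pd.DataFrame(q[:, 1:], columns=["x1", "x2", "x3"])
        t["y"] = rng.normal(size=n)
        res = fit_mlr(ModelSpec("O", "y", ("x1", "x2", "x3")), t)
        assert np.allclose(res.vif().to_numpy(), 1.0, atol=1e-8)

    def test_m5_max_vif_matches_statsmodels(self, m5_results):
        X = m5_results.model.exog.to_numpy(float)
        oracle = max(variance_inflation_factor(X, j) for j in range(1, X.shape[1]))
        assert m5_results.max_vif == pytest.approx(oracle, rel=1e-8)
        assert round(m5_results.max_vif, 1) == 4.8

    def test_near_duplicate_predictor_flags_infinite_vif(self, table3):
        t = table3.copy()
        t["mw2"] = t["mw"] * 2.0 + 1e-9 * np.arange(len(t))  # keep design full rank
        res = fit_mlr(ModelSpec("C", "log_bb", ("mw", "mw2", "hba")), t)
        stats = res.stats()
        assert stats.infinite_vif or stats.max_vif > 1e6


class TestStandardizedCoefficients:
    def test_predictor_equal_to_response(self, table3):
        t = table3.copy()
        t["y"] = t["mw"]
        res = fit_mlr(ModelSpec("S", "y", ("mw", "hba")), t)
        assert res.standardized_coefficients()["mw"] == pytest.approx(1.0, abs=1e-10)

    def test_scale_invariance(self, table3, m5_results):
        t = table3.copy()
        t["parachor_P"] = t["parachor_P"] * 10.0
        res = fit_mlr(m5_results.spec, t)
        assert res.standardized_coefficients()["parachor_P"] == pytest.approx(
            m5_results.standardized_coefficients()["parachor_P"], rel=1e-10
        )

    def test_hba_dominates_m5(self, m5_results):
        """Hydrogen-bond acceptor count is the dominant influence on log BB."""
        b = m5_results.standardized_coefficients().abs()
        assert b.idxmax() == "hba"

    def test_sign_matches_raw_coefficient(self, m5_results):
        b = m5_results.standardized_coefficients()
        for name in m5_results.spec.predictors:
            assert np.sign(b[name]) == np.sign(m5_results.params[name])


@pytest.fixture(scope="module")
def all_stats(table3):
    specs = enumerate_models(PAPER_GROUPS, include_flexibility="both")
    return [QSARModel(s, table3).fit().stats() for s in specs]


class TestScreening:

    def test_exclusion_set_reproduced(self, all_stats):
        screening = screen_models(all_stats)
        assert set(screening.excluded) == {"M1", "M3", "M4", "M7", "M9", "M10"}

    def test_winners_shortlisted(self, all_stats):
        screening = screen_models(all_stats)
        shortlist = screening.shortlist
        assert "M5" in shortlist and "M11" in shortlist and "M12" in shortlist
        by_resp = {}
        for s in screening.ranked:
            by_resp.setdefault(s.response, s.label)
        assert by_resp["log_bb"] in {"M5", "M5*"}

    def test_ranking_by_predictive_r2(self, all_stats):
        screening = screen_models(all_stats)
        pred = [s.r2_pred for s in screening.ranked]
        assert pred == sorted(pred, reverse=True)

    def test_press_ss_threshold_flags(self, all_stats):
        bad = all_stats[0]
        import copy

        s = copy.copy(bad)
        s.label, s.press, s.max_vif = "BAD", 0.5 * s.ss, 1.0
        s.q2_loo = 1.0 - 0.5
        s.press_ss_ratio = 0.5
        screening = screen_models([s])
        assert screening.flagged == ["BAD"]

    def test_empty_input_rejected(self):
        with pytest.raises(errors.ValidationError):
            screen_models([])


class TestPredict:
    def test_training_compound_prediction(self, table3, m5_results):
        row = table3.iloc[0]
        yhat, lev, in_domain = m5_results.predict(row)
        assert yhat == pytest.approx(row["log_bb"] - m5_results.resid[0], abs=1e-10)
        assert lev == pytest.approx(m5_results.leverages[0], abs=1e-10)
        assert in_domain

    def test_centroid_has_minimal_leverage(self, table3, m5_results):
        centroid = {p: table3[p].mean() for p in m5_results.spec.predictors}
        _, lev, in_domain = m5_results.predict(centroid)
        assert lev == pytest.approx(1.0 / m5_results.nobs, abs=1e-12)
        assert in_domain

    def test_far_record_out_of_domain(self, table3, m5_results):
        far = {p: table3[p].max() * 10 for p in m5_results.spec.predictors}
        _, lev, in_domain = m5_results.predict(far)
        assert not in_domain

    def test_missing_predictor(self, m5_results):
        with pytest.raises(errors.ValidationError, match="hba"):
            m5_results.predict({"log_km_over_kam": -0.5})


class TestParameterRecovery:
    def test_coefficients_within_3se_of_truth(self, table3):
        """Synthetic responses on the real design: ~99.7% coverage at +/-3 SE."""
        truth = {"const": 0.25, "log_km_over_kam": 0.2, "hba": -0.16, "nrb": -0.02, "parachor_P": 0.002}
        rng = np.random.default_rng(42)
        names = ["const", "log_km_over_kam", "hba", "nrb", "parachor_P"]
        hits = total = 0
        for _ in range(100):
            t = table3.copy()
            t["y"] = (
                truth["const"]
                + sum(truth[k] * t[k] for k in names[1:])
                + rng.normal(0.0, 0.08, size=len(t))
            )
            res = fit_mlr(ModelSpec("T", "y", tuple(names[1:])), t)
            for k in names:
                hits += abs(res.params[k] - truth[k]) <= 3 * res.bse[k]
                total += 1
        assert hits / total >= 0.98
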