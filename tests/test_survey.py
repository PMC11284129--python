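"""Survey-weighted logistic and Cox solvers against independent oracles."""

import logging

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from lifelines import CoxPHFitter

from oxbal.survey import (
    SeparationError,
    SurveyDesign,
    ZeroEventsError,
    build_design_matrix,
    fit_weighted_cox,
    fit_weighted_logistic,
    interaction_test,
    trend_test,
    wald_test,
)
from oxbal.survey import test_nonlinearity as nonlinearity_wald_p  # avoid pytest collection


def _duplicate_rows(y, X, w):
    idx = np.repeat(np.arange(len(y)), w.astype(int))
    return y[idx], X.iloc[idx].reset_index(drop=True), idx


class TestWeightedLogistic:
    def test_matches_ml_oracle_under_iid_design(self, logistic_sim):
        y, X = logistic_sim
        fit = fit_weighted_logistic(y, X, SurveyDesign.iid(len(y)))
        oracle = sm.Logit(y, X).fit(disp=0)
        rel = np.abs(fit.params.to_numpy() - oracle.params.to_numpy()) / (
            np.abs(oracle.params.to_numpy()) + 1e-12
        )
        assert rel.max() < 1e-6

    def test_integer_weights_equal_row_duplication(self, logistic_sim, rng):
        y, X = logistic_sim
        w = rng.integers(1, 5, len(y)).astype(float)
        design_w = SurveyDesign(np.zeros(len(y)), np.arange(len(y)), w)
        fit_w = fit_weighted_logistic(y, X, design_w)
        y_d, X_d, _ = _duplicate_rows(y, X, w)
        fit_d = fit_weighted_logistic(y_d, X_d, SurveyDesign.iid(len(y_d)))
        np.testing.assert_allclose(fit_w.params, fit_d.params, atol=1e-9)

    def test_design_collapse_to_robust_se(self, logistic_sim):
        """One stratum + singleton PSUs + unit weights = HC0 x n/(n-1)."""
        y, X = logistic_sim
        n = len(y)
        fit = fit_weighted_logistic(y, X, SurveyDesign.iid(n))
        oracle = sm.Logit(y, X).fit(disp=0, cov_type="HC0")
        expected = oracle.bse.to_numpy() * np.sqrt(n / (n - 1))
        np.testing.assert_allclose(fit.se.to_numpy(), expected, rtol=1e-6)

    def test_effect_is_exactly_exp_of_coefficient(self, logistic_sim):
        y, X = logistic_sim
        fit = fit_weighted_logistic(y, X, SurveyDesign.iid(len(y)))
        assert (fit.effects == np.exp(fit.params)).all()
        ci = fit.conf_int()
        assert (ci["low"] < fit.effects).all() and (fit.effects < ci["high"]).all()

    def test_separation_detected(self):
        n = 60
        x = np.linspace(-2, 2, n)
        y = (x > 0).astype(float)
        X = pd.DataFrame({"intercept": np.ones(n), "x": x})
        with pytest.raises(SeparationError):
            fit_weighted_logistic(y, X, SurveyDesign.iid(n))

    def test_rank_deficiency_rejected(self, logistic_sim):
        y, X = logistic_sim
        X2 = X.copy()
        X2["dup"] = X2["x1"]
        with pytest.raises(ValueError, match="rank"):
            fit_weighted_logistic(y, X2, SurveyDesign.iid(len(y)))

    def test_lonely_psu_warns(self, logistic_sim, caplog):
        y, X = logistic_sim
        n = len(y)
        stratum = np.zeros(n, dtype=int)
        stratum[0] = 99  # one stratum with a single PSU
        psu = np.arange(n)
        design = SurveyDesign(stratum, psu, np.ones(n))
        with caplog.at_level(logging.WARNING, logger="oxbal.survey"):
            fit_weighted_logistic(y, X, design)
        assert any("single PSU" in r.message for r in caplog.records)


class TestWeightedCox:
    def test_matches_partial_likelihood_oracle(self, cox_sim):
        time, event, X = cox_sim
        fit = fit_weighted_cox(time, event, X, SurveyDesign.iid(len(time)))
        df = pd.DataFrame({"t": time, "e": event, **{c: X[c] for c in X}})
        oracle = CoxPHFitter().fit(df, "t", "e", fit_options={"precision": 1e-9})
        rel = np.abs(fit.params.to_numpy() - oracle.params_.to_numpy()) / np.abs(
            oracle.params_.to_numpy()
        )
        assert rel.max() < 1e-6

    def test_integer_weights_equal_row_duplication(self, cox_sim, rng):
        time, event, X = cox_sim
        w = rng.integers(1, 4, len(time)).astype(float)
        fit_w = fit_weighted_cox(
            time, event, X, SurveyDesign(np.zeros(len(time)), np.arange(len(time)), w)
        )
        idx = np.repeat(np.arange(len(time)), w.astype(int))
        fit_d = fit_weighted_cox(
            time[idx], event[idx], X.iloc[idx].reset_index(drop=True),
            SurveyDesign.iid(len(idx)),
        )
        np.testing.assert_allclose(fit_w.params, fit_d.params, atol=1e-8)

    def test_zero_events_rejected(self, cox_sim):
        time, event, X = cox_sim
        with pytest.raises(ZeroEventsError):
            fit_weighted_cox(time, np.zeros_like(event), X, SurveyDesign.iid(len(time)))

    def test_null_two_group_hazard_ratio_near_one(self, rng):
        n = 4000
        t = rng.exponential(1.0, n)
        g = (rng.random(n) < 0.5).astype(float)
        X = pd.DataFrame({"group": g})
        fit = fit_weighted_cox(t, np.ones(n), X, SurveyDesign.iid(n))
        hr = float(np.exp(fit.params["group"]))
        assert abs(hr - 1.0) < 3 * float(fit.se["group"])

    def test_breslow_ties_match_lifelines(self, rng):
        """Heavily tied data: Breslow convention against the lifelines oracle."""
        n = 300
        x = rng.normal(size=n)
        t = rng.integers(1, 8, n).astype(float)  # many ties
        e = (rng.random(n) < 0.7).astype(float)
        X = pd.DataFrame({"x": x})
        fit = fit_weighted_cox(t, e, X, SurveyDesign.iid(n))
        df = pd.DataFrame({"t": t, "e": e, "x": x})
        oracle = CoxPHFitter(baseline_estimation_method="breslow").fit(df, "t", "e")
        # lifelines uses the Efron tie correction internally; Breslow and
        # Efron must agree closely at this tie density but not exactly
        assert fit.params["x"] == pytest.approx(oracle.params_["x"], abs=0.05)


class TestWaldMachinery:
    def test_trend_p_affine_invariant(self, rng):
        n = 1200
        q = rng.integers(0, 4, n)
        y = (rng.random(n) < 0.3 + 0.05 * q).astype(float)
        design = SurveyDesign.iid(n)
        ps = []
        for codes in (q + 1.0, q.astype(float), 10.0 + 2.0 * q):
            X = pd.DataFrame({"intercept": np.ones(n), "ordinal": codes})
            fit = fit_weighted_logistic(y, X, design)
            ps.append(float(fit.pvalues["ordinal"]))
        assert ps[0] == pytest.approx(ps[1], rel=1e-8)
        assert ps[0] == pytest.approx(ps[2], rel=1e-8)

    def test_trend_requires_two_levels(self, rng):
        n = 100
        with pytest.raises(ValueError, match="quartile"):
            trend_test(
                np.zeros(n), pd.Categorical(["Q1"] * n), None, SurveyDesign.iid(n)
            )

    def test_interaction_constant_modifier_rejected(self, rng):
        n = 100
        with pytest.raises(ValueError, match="constant"):
            interaction_test(
                np.zeros(n), rng.normal(size=n), np.ones(n), None, SurveyDesign.iid(n)
            )

    def test_nonlinearity_requires_nonlinear_terms(self, logistic_sim):
        y, X = logistic_sim
        fit = fit_weighted_logistic(y, X, SurveyDesign.iid(len(y)))
        with pytest.raises(ValueError, match="nonlinear"):
            nonlinearity_wald_p(fit)

    def test_wald_single_term_matches_z_test(self, logistic_sim):
        y, X = logistic_sim
        fit = fit_weighted_logistic(y, X, SurveyDesign.iid(len(y)))
        stat, p, df = wald_test(fit, ["x1"])
        assert df == 1
        assert p == pytest.approx(float(fit.pvalues["x1"]), rel=1e-10)


class TestDesignMatrix:
    def test_categoricals_dummy_coded(self):
        df = pd.DataFrame({"a": ["x", "y", "z", "x"], "b": [1.0, 2.0, 3.0, 4.0]})
        X = build_design_matrix(df, ["a", "b"])
        assert list(X.columns) == ["intercept", "a_y", "a_z", "b"]
        assert X["a_y"].tolist() == [0.0, 1.0, 0.0, 0.0]

    def test_design_requires_positive_weights(self):
        with pytest.raises(ValueError, match="weights"):
            SurveyDesign(np.zeros(3), np.arange(3), np.array([1.0, 0.0, 2.0]))
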