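"""Design-based WLS, transform ladder, LSMs, and Tukey-Kramer comparisons."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from bevclass.survey import (
    OutcomeModel,
    SingularDesignError,
    SurveyDesign,
    SurveyWLS,
    build_design_matrix,
    choose_transform,
    letter_display,
    lsm,
    tukey_pairwise,
    weighted_skewness,
)


@pytest.fixture
def regression_data():
    rng = np.random.default_rng(42)
    n = 80
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
    y = X @ np.array([1.0, 2.0, -1.0]) + rng.normal(size=n)
    w = rng.uniform(0.5, 2.0, n)
    return X, y, w


def _srs(n, w=None):
    return SurveyDesign(strata=np.zeros(n), psu=np.arange(n), weights=np.ones(n) if w is None else w)


class TestSurveyWLS:
    def test_srs_collapse_matches_textbook_wls(self, regression_data):
        X, y, w = regression_data
        fit = SurveyWLS().fit(X, y, _srs(len(y), w))
        ref = sm.WLS(y, X, weights=w).fit()
        assert np.allclose(fit.params_, ref.params, atol=1e-10)

    def test_srs_collapse_ses_are_robust_ses(self, regression_data):
        # With one stratum and singleton PSUs the linearized covariance is
        # the centered sandwich: HC0 scaled by n/(n-1).
        X, y, w = regression_data
        n = len(y)
        fit = SurveyWLS().fit(X, y, _srs(n, w))
        hc0 = sm.WLS(y, X, weights=w).fit(cov_type="HC0")
        assert np.allclose(fit.bse_, hc0.bse * np.sqrt(n / (n - 1)), rtol=1e-10)

    def test_two_strata_design_matches_linearization_oracle(self, regression_data):
        X, y, w = regression_data
        n, p = X.shape
        rng = np.random.default_rng(1)
        strata = rng.integers(0, 2, n)
        psu = rng.integers(0, 3, n)
        fit = SurveyWLS().fit(X, y, SurveyDesign(strata=strata, psu=psu, weights=w))

        # Brute-force oracle from per-PSU score totals.
        beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
        scores = (w * (y - X @ beta))[:, None] * X
        G = np.zeros((p, p))
        n_psu = 0
        for h in np.unique(strata):
            z = []
            for j in np.unique(psu[strata == h]):
                z.append(scores[(strata == h) & (psu == j)].sum(axis=0))
                n_psu += 1
            z = np.array(z)
            dev = z - z.mean(axis=0)
            G += len(z) / (len(z) - 1) * dev.T @ dev
        A_inv = np.linalg.inv(X.T @ (w[:, None] * X))
        oracle = A_inv @ G @ A_inv
        assert np.allclose(fit.cov_params_, oracle, atol=1e-12)
        assert fit.df_resid_ == n_psu - 2

    def test_constant_outcome_has_zero_slopes_and_ses(self, regression_data):
        X, _, w = regression_data
        y = np.full(X.shape[0], 7.0)
        fit = SurveyWLS().fit(X, y, _srs(len(y), w))
        assert np.allclose(fit.params_[1:], 0.0, atol=1e-10)
        assert np.allclose(fit.bse_, 0.0, atol=1e-10)

    def test_weight_scale_equivariance(self, regression_data):
        X, y, w = regression_data
        des1 = _srs(len(y), w)
        des2 = _srs(len(y), 17.3 * w)
        f1 = SurveyWLS().fit(X, y, des1)
        f2 = SurveyWLS().fit(X, y, des2)
        assert np.allclose(f1.params_, f2.params_, rtol=1e-10)
        assert np.allclose(f1.bse_, f2.bse_, rtol=1e-10)

    def test_singular_design_names_aliased_column(self, regression_data):
        X, y, w = regression_data
        X2 = np.column_stack([X, X[:, 1]])
        with pytest.raises(SingularDesignError, match="dup"):
            SurveyWLS().fit(X2, y, _srs(len(y), w), colnames=["i", "a", "b", "dup"])

    def test_lonely_psu_logged_and_centered(self, regression_data):
        X, y, w = regression_data
        n = len(y)
        strata = np.zeros(n)
        strata[:5] = 1  # stratum 1 holds a single PSU
        psu = np.arange(n) % 7
        psu[:5] = 0
        fit = SurveyWLS().fit(X, y, SurveyDesign(strata=strata, psu=psu, weights=w))
        assert fit.lonely_strata_ == [1.0]
        assert np.all(np.isfinite(fit.bse_))
        with pytest.raises(ValueError, match="single PSU"):
            SurveyWLS(lonely_psu="error").fit(X, y, SurveyDesign(strata=strata, psu=psu, weights=w))


class TestTransformLadder:
    def _design(self, n):
        return np.ones((n, 1)), _srs(n)

    def test_symmetric_outcome_stays_identity(self):
        rng = np.random.default_rng(0)
        y = rng.normal(100.0, 5.0, 500)
        X, des = self._design(len(y))
        name, _ = choose_transform(y, X, des)
        assert name == "identity"

    def test_lognormal_outcome_selects_log(self):
        rng = np.random.default_rng(0)
        y = np.exp(rng.normal(7.0, 0.8, 800))
        X, des = self._design(len(y))
        name, _ = choose_transform(y, X, des)
        assert name == "log"

    def test_constant_outcome_identity_zero_skewness(self):
        y = np.full(50, 3.0)
        X, des = self._design(50)
        name, fit = choose_transform(y, X, des)
        assert name == "identity"
        assert weighted_skewness(fit.resid_, des.weights) == 0.0

    def test_nonpositive_outcomes_reject_log_rungs(self):
        rng = np.random.default_rng(3)
        y = np.concatenate([[-5.0], np.exp(rng.normal(0, 2.0, 400))])
        X, des = self._design(len(y))
        name, _ = choose_transform(y, X, des)
        # a negative outcome bars every power/log rung, so identity remains
        assert name == "identity"


class TestLsm:
    def _frame(self, rng, n=120, delta=0.0):
        g = rng.choice(["a", "b", "c"], size=n)
        y = 10.0 + delta * (g == "b") + rng.normal(0, 1, n)
        w = rng.uniform(0.5, 2.0, n)
        return pd.DataFrame({"group": g, "y": y, "w": w})

    def test_no_covariates_equals_weighted_group_means(self):
        rng = np.random.default_rng(5)
        df = self._frame(rng)
        X, info = build_design_matrix(df, [], ["group"])
        des = _srs(len(df), df["w"].to_numpy())
        fit = SurveyWLS().fit(X, df["y"].to_numpy(), des)
        means, _ = lsm(fit, info, df, des.weights, "group", ["a", "b", "c"])
        for i, g in enumerate(["a", "b", "c"]):
            sub = df[df["group"] == g]
            assert means[i] == pytest.approx(np.average(sub["y"], weights=sub["w"]), abs=1e-10)

    def test_planted_effect_recovered_within_ci(self):
        rng = np.random.default_rng(6)
        df = self._frame(rng, n=400, delta=2.0)
        X, info = build_design_matrix(df, [], ["group"])
        des = _srs(len(df), df["w"].to_numpy())
        fit = SurveyWLS().fit(X, df["y"].to_numpy(), des)
        means, cov = lsm(fit, info, df, des.weights, "group", ["a", "b"])
        d = means[1] - means[0]
        se = np.sqrt(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
        assert abs(d - 2.0) < 3 * se

    def test_identical_groups_have_zero_differences(self):
        df = pd.DataFrame({"group": ["a"] * 5 + ["b"] * 5, "y": [4.0] * 10, "w": [1.0] * 10})
        X, info = build_design_matrix(df, [], ["group"])
        des = _srs(10)
        fit = SurveyWLS().fit(X, df["y"].to_numpy(), des)
        means, cov = lsm(fit, info, df, des.weights, "group", ["a", "b"])
        pw = tukey_pairwise(means, cov, fit.df_resid_, ["a", "b"])
        assert pw.loc[0, "estimate"] == pytest.approx(0.0, abs=1e-10)
        assert pw.loc[0, "p_adj"] == 1.0

    def test_absent_group_raises(self):
        df = pd.DataFrame({"group": ["a"] * 6, "y": np.arange(6.0), "w": np.ones(6)})
        X, info = build_design_matrix(df, [], ["group"])
        fit = SurveyWLS().fit(X, df["y"].to_numpy(), _srs(6))
        with pytest.raises(ValueError, match="absent"):
            lsm(fit, info, df, np.ones(6), "group", ["a", "zz"])


class TestTukey:
    def test_two_groups_reduce_to_t_test(self):
        means = np.array([0.0, 1.3])
        cov = np.array([[0.2, 0.05], [0.05, 0.3]])
        pw = tukey_pairwise(means, cov, 25, ["a", "b"])
        t = pw.loc[0, "t"]
        assert pw.loc[0, "p_adj"] == pytest.approx(2 * stats.t.sf(abs(t), 25), rel=1e-9)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            tukey_pairwise(np.array([1.0]), np.array([[1.0]]), 10, ["a"])

    def test_adjusted_p_never_below_unadjusted(self):
        rng = np.random.default_rng(8)
        k = 4
        means = rng.normal(size=k)
        A = rng.normal(size=(k, k))
        cov = A @ A.T / 10
        pw = tukey_pairwise(means, cov, 12, list("abcd"))
        assert (pw["p_adj"] >= pw["p_unadj"] - 1e-12).all()

    def test_one_shifted_group_letter_pattern(self):
        rng = np.random.default_rng(9)
        n = 400
        g = np.repeat(["a", "b", "c", "d"], n // 4)
        y = np.where(g == "d", 50.0, 0.0) + rng.normal(0, 1, n)
        df = pd.DataFrame({"group": g, "y": y})
        X, info = build_design_matrix(df, [], ["group"])
        des = _srs(n)
        fit = SurveyWLS().fit(X, df["y"].to_numpy(), des)
        groups = ["a", "b", "c", "d"]
        means, cov = lsm(fit, info, df, des.weights, "group", groups)
        pw = tukey_pairwise(means, cov, fit.df_resid_, groups)
        letters = letter_display(groups, dict(zip(groups, means)), pw)
        assert letters["a"] == letters["b"] == letters["c"]
        assert letters["d"] != letters["a"]


class TestOutcomeModel:
    def test_fits_small_world_and_reports_four_groups(self, small_world, small_world_tab):
        from bevclass.recall import Scenario, assign_groups, build_participant_days

        _, foodcodes, _, participants, recalls, _ = small_world
        days = build_participant_days(participants, recalls, small_world_tab, foodcodes)
        days = assign_groups(days, Scenario.MIXED_AS_LCSB)
        frame = days.merge(participants, on="participant_id", how="left")
        om = OutcomeModel("energy_kcal", model=1).fit(frame)
        assert set(om.groups_) == {"WATER", "LCSB", "SB", "LCSB_SB"}
        assert all(se > 0 for se in om.lsm_se_.values())
        assert om.df_resid_ == om.fit_raw_.n_psu_ - om.fit_raw_.n_strata_

    def test_energy_cannot_be_its_own_adjustment(self):
        with pytest.raises(ValueError, match="Model 2"):
            OutcomeModel("energy_kcal", model=2).fit(pd.DataFrame())
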