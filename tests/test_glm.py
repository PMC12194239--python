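"""Count-model likelihoods, fitting, overdispersion, and AIC model selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import approx_fprime

from urchindrift.errors import DataError
from urchindrift.glm import (
    LEVELS,
    CountModelFit,
    TrapHaulTable,
    _nll_and_grad,
    design_matrix,
    fit_count_model,
    ladder_formulas,
    model_selection,
    overdispersion_check,
    zinb_loglik,
    zinb_zero_probability,
)
from urchindrift.synthetic import default_catch_scenario, make_trap_table


def small_table(n=400, seed=0):
    return make_trap_table(default_catch_scenario(n_records=n, seed=seed))


class TestTrapHaulTable:
    def test_unknown_level_rejected(self):
        tab = small_table(50)
        df = tab.data.copy()
        df.loc[0, "zone"] = "RC_Z"
        with pytest.raises(DataError, match="zone"):
            TrapHaulTable(df)

    def test_negative_count_rejected(self):
        tab = small_table(50)
        df = tab.data.copy()
        df.loc[0, "urchin_count"] = -1
        with pytest.raises(DataError, match="non-negative"):
            TrapHaulTable(df)

    def test_csv_round_trip(self, tmp_path):
        tab = small_table(80)
        p = tmp_path / "hauls.csv"
        tab.to_csv(p)
        back = TrapHaulTable.from_csv(p)
        pd.testing.assert_frame_equal(
            back.data, tab.data, check_dtype=False
        )


class TestDesignMatrix:
    def test_two_level_predictor_gives_two_columns(self):
        tab = small_table(60)
        X, names = design_matrix(tab, ("size",))
        assert X.shape == (60, 2)
        assert names == ["intercept", "size[small]"]

    def test_reference_row_is_intercept_only(self):
        df = pd.DataFrame({
            "year": ["2015"], "month": ["October"], "zone": ["RC_A"],
            "depth_stratum": ["0-50"], "lobster_size": ["large"],
            "urchin_count": [0],
        })
        X, _ = design_matrix(TrapHaulTable(df), tuple(LEVELS))
        np.testing.assert_array_equal(X[0], np.eye(X.shape[1])[0])

    def test_full_design_parameter_count(self):
        """Intercept + 7 year + 7 month + 5 zone + 3 depth + 1 size = 24
        coefficients; phi and pi make 26 for the ZINB."""
        tab = small_table(200)
        X, _ = design_matrix(tab, tuple(LEVELS))
        assert X.shape[1] == 24


class TestZINBLoglik:
    def test_reduces_to_nb_at_pi_zero(self):
        rng = np.random.default_rng(1)
        y = rng.poisson(2.0, 50)
        X = np.column_stack([np.ones(50), rng.normal(size=50)])
        beta = np.array([0.5, 0.2])
        from urchindrift.glm import _nb_logpmf

        mu = np.exp(X @ beta)
        expect = _nb_logpmf(y, mu, 1.3).sum()
        assert zinb_loglik(y, X, beta, 1.3, 0.0) == pytest.approx(expect, rel=1e-12)

    def test_hand_value_single_zero(self):
        """y=0, lambda=1, phi=1, pi=0.5: NB(0;1,1) = 1/2, so the likelihood
        is log(0.5 + 0.5 * 0.5) = log(0.75)."""
        ll = zinb_loglik(np.array([0]), np.array([[1.0]]), np.array([0.0]),
                         1.0, 0.5)
        assert ll == pytest.approx(np.log(0.75), rel=1e-12)

    @pytest.mark.parametrize("phi,pi", [(0.7, 0.0), (1.5, 0.3), (4.0, 0.8)])
    def test_normalizes_over_support(self, phi, pi):
        """Per-record probabilities sum to 1 over y = 0..K by brute force."""
        X = np.array([[1.0, 0.5]])
        beta = np.array([0.4, 0.3])
        total = 0.0
        for k in range(2000):
            total += np.exp(zinb_loglik(np.array([k]), X, beta, phi, pi))
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_zip_limit_at_large_phi(self):
        """phi -> inf: ZINB collapses onto the ZIP likelihood per record."""
        rng = np.random.default_rng(3)
        y = rng.poisson(1.5, 30).astype(float)
        X = np.ones((30, 1))
        beta = np.array([0.3])
        pi = 0.25
        th_zip = np.array([0.3, np.log(pi / (1 - pi))])
        zip_ll = -_nll_and_grad(th_zip, y, X, "zip")[0]
        zinb_ll = zinb_loglik(y.astype(int), X, beta, 1e6, pi)
        assert abs(zinb_ll - zip_ll) / len(y) < 1e-4

    def test_negative_count_rejected(self):
        with pytest.raises(DataError):
            zinb_loglik(np.array([-1]), np.ones((1, 1)), np.zeros(1), 1.0, 0.1)

    def test_zero_probability_oracle_matches_loglik(self):
        mu = np.array([0.5, 2.0, 7.0])
        phi, pi = 1.2, 0.4
        X = np.log(mu)[:, None]
        for i, m in enumerate(mu):
            p0 = np.exp(zinb_loglik(np.array([0]), X[i:i + 1], np.array([1.0]),
                                    phi, pi))
            assert p0 == pytest.approx(zinb_zero_probability(m, phi, pi), rel=1e-12)


class TestGradients:
    @pytest.mark.parametrize("family,extra", [("poisson", 0), ("nb", 1),
                                              ("zip", 1), ("zinb", 2)])
    def test_analytic_gradient_matches_numeric(self, family, extra):
        tab = small_table(300, seed=2)
        y = tab.counts.astype(float)
        X, _ = design_matrix(tab, ("depth", "size"))
        rng = np.random.default_rng(4)
        theta = 0.1 * rng.standard_normal(X.shape[1] + extra)
        g_num = approx_fprime(theta, lambda t: _nll_and_grad(t, y, X, family)[0],
                              1e-6)
        g_an = _nll_and_grad(theta, y, X, family)[1]
        np.testing.assert_allclose(g_an, g_num, rtol=1e-4, atol=1e-3)


class TestFitting:
    def test_intercept_only_poisson_closed_form(self):
        tab = small_table(500, seed=5)
        fit = fit_count_model(tab, (), "poisson")
        assert fit.coefficients["intercept"] == pytest.approx(
            np.log(tab.counts.mean()), rel=1e-6
        )
        assert fit.df == 1

    def test_aic_identity_all_families(self):
        tab = small_table(500, seed=6)
        for family in ("poisson", "zip", "nb", "zinb"):
            fit = fit_count_model(tab, ("size",), family)
            assert fit.aic == pytest.approx(2 * fit.df - 2 * fit.loglik, rel=1e-12)
            assert (fit.pi is not None) == (family in ("zip", "zinb"))
            assert (fit.phi is not None) == (family in ("nb", "zinb"))

    def test_poisson_recovery_matches_statsmodels(self):
        """Cross-check against the GLM fit of an independent implementation."""
        import statsmodels.api as sm

        tab = small_table(2000, seed=7)
        fit = fit_count_model(tab, ("year", "size"), "poisson")
        X, _ = design_matrix(tab, ("year", "size"))
        ref = sm.GLM(tab.counts, X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fit.coefficients.to_numpy(), ref.params,
                                   rtol=1e-5, atol=1e-6)
        assert fit.loglik == pytest.approx(ref.llf, rel=1e-8)

    def test_zinb_fit_matches_statsmodels(self):
        """Full ZINB maximum likelihood against the reference implementation
        (its alpha is 1/phi; its inflation logit matches logit(pi))."""
        import statsmodels.api as sm

        tab = small_table(3000, seed=8)
        fit = fit_count_model(tab, ("depth", "size"), "zinb")
        X, _ = design_matrix(tab, ("depth", "size"))
        ref = sm.ZeroInflatedNegativeBinomialP(
            tab.counts, X, exog_infl=np.ones((len(tab), 1)), p=2
        ).fit(maxiter=500, disp=0)
        assert fit.loglik == pytest.approx(ref.llf, abs=0.05)
        np.testing.assert_allclose(fit.coefficients.to_numpy(),
                                   ref.params[1:-1], atol=0.02)
        assert fit.phi == pytest.approx(1.0 / ref.params[-1], rel=0.05)
        pi_ref = 1.0 / (1.0 + np.exp(-ref.params[0]))
        assert fit.pi == pytest.approx(pi_ref, abs=0.01)

    def test_zinb_recovers_truth_at_n_10000(self):
        scen = default_catch_scenario(n_records=10_000, seed=11)
        tab = make_trap_table(scen)
        fit = fit_count_model(tab, tuple(LEVELS), "zinb")
        assert fit.converged
        assert abs(fit.pi - scen.pi) < 0.05
        assert abs(fit.coefficients["year[2021]"] - 2.2) < 0.2

    def test_optimum_not_worse_than_warm_start(self):
        from urchindrift.glm import _poisson_warm_start

        tab = small_table(800, seed=9)
        y = tab.counts.astype(float)
        X, _ = design_matrix(tab, ("zone",))
        fit = fit_count_model(tab, ("zone",), "zinb")
        beta0 = _poisson_warm_start(y, X)
        start = np.concatenate([beta0, [0.0, 0.0]])
        assert fit.loglik >= -_nll_and_grad(start, y, X, "zinb")[0] - 1e-9

    def test_too_few_records_rejected(self):
        tab = small_table(20)
        with pytest.raises(DataError):
            fit_count_model(tab, tuple(LEVELS), "zinb")


class TestOverdispersion:
    def test_equidispersed_poisson_near_one(self):
        rng = np.random.default_rng(10)
        n = 5000
        df = pd.DataFrame({
            "year": rng.choice(LEVELS["year"], n),
            "month": rng.choice(LEVELS["month"], n),
            "zone": rng.choice(LEVELS["zone"], n),
            "depth_stratum": rng.choice(LEVELS["depth"], n),
            "lobster_size": rng.choice(LEVELS["size"], n),
            "urchin_count": rng.poisson(3.0, n),
        })
        fit = fit_count_model(TrapHaulTable(df), (), "poisson")
        stat = overdispersion_check(fit, TrapHaulTable(df))
        assert 0.9 < stat < 1.1

    def test_nb_data_fitted_as_poisson_flags_overdispersion(self):
        rng = np.random.default_rng(11)
        n = 5000
        phi = 0.5
        mu = 3.0
        y = rng.negative_binomial(phi, phi / (phi + mu), n)
        df = pd.DataFrame({
            "year": ["2015"] * n, "month": ["October"] * n, "zone": ["RC_A"] * n,
            "depth_stratum": ["0-50"] * n, "lobster_size": ["large"] * n,
            "urchin_count": y,
        })
        tab = TrapHaulTable(df)
        stat = overdispersion_check(fit_count_model(tab, (), "poisson"), tab)
        assert stat > 1.5

    def test_saturated_toy_is_zero(self):
        df = pd.DataFrame({
            "year": ["2015"] * 4, "month": ["October"] * 4, "zone": ["RC_A"] * 4,
            "depth_stratum": ["0-50"] * 4, "lobster_size": ["large"] * 4,
            "urchin_count": [3, 3, 3, 3],
        })
        tab = TrapHaulTable(df)
        fit = CountModelFit(
            family="poisson", predictors=(), coefficients=pd.Series([np.log(3.0)],
            index=["intercept"]), phi=None, pi=None, loglik=0.0, aic=0.0, df=1,
            converged=True, n=4, fitted_mean=np.full(4, 3.0),
        )
        assert overdispersion_check(fit, tab) == 0.0


class TestModelSelection:
    def test_ladder_structure(self):
        names = [name for name, _ in ladder_formulas()]
        assert names == ["m1", "m2", "m3", "m4", "m5", "M1", "M2", "M3", "M4", "M5"]
        preds = dict(ladder_formulas())
        assert preds["M5"] == ("year", "month", "zone", "depth", "size")
        assert preds["m3"] == ("zone",)

    def test_full_model_wins_on_full_model_data(self):
        tab = make_trap_table(default_catch_scenario(n_records=10_000, seed=12))
        ranking = model_selection(tab, family="zinb")
        assert ranking.iloc[0]["model"] == "M5"
        # ranked ascending by AIC
        assert ranking["aic"].is_monotonic_increasing

    def test_duplicate_candidates_tie_on_aic(self):
        tab = small_table(600, seed=13)
        ranking = model_selection(
            tab, candidates=[("a", ("size",)), ("b", ("size",))], family="nb"
        )
        assert ranking.iloc[0]["aic"] == pytest.approx(ranking.iloc[1]["aic"])

    def test_tie_broken_by_fewer_parameters(self):
        tab = small_table(600, seed=13)
        rows = pd.DataFrame({
            "model": ["big", "small"], "df": [5, 2], "aic": [100.0, 100.0],
        })
        ranked = rows.sort_values(["aic", "df"], kind="stable")
        assert ranked.iloc[0]["model"] == "small"

    def test_single_candidate_ranked_first(self):
        tab = small_table(600, seed=14)
        ranking = model_selection(tab, candidates=[("only", ("size",))],
                                  family="poisson")
        assert len(ranking) == 1 and ranking.iloc[0]["model"] == "only"

    def test_unfittable_candidate_does_not_break_ladder(self):
        tab = small_table(25, seed=15)  # too few records for the 24-column design
        ranking = model_selection(
            tab,
            candidates=[("ok", ("size",)), ("toobig", tuple(LEVELS))],
            family="nb",
        )
        assert set(ranking["model"]) == {"ok", "toobig"}
        bad = ranking[ranking["model"] == "toobig"].iloc[0]
        assert bad["status"].startswith("error")
        assert ranking.iloc[0]["model"] == "ok"
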