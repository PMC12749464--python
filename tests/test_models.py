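"""Outcome-model MLEs: closed forms, cross-checks, series, interactions, IPW."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import approx_fprime
from scipy.special import expit

from partnerseq import models as M
from partnerseq import simulate


@pytest.fixture(scope="module")
def analytic_data():
    return simulate.simulate_cohort(simulate.GeneratorConfig(n=2000, seed=3)).data


def simulate_ordered(rng, n, beta, kappa):
    X = rng.normal(size=(n, len(beta)))
    eta = X @ beta
    cdf = expit(np.asarray(kappa)[None, :] - eta[:, None])
    y = (rng.random(n)[:, None] > cdf).sum(axis=1)
    return y, X


def simulate_nb2(rng, n, beta, alpha, X=None):
    if X is None:
        X = np.column_stack([np.ones(n), rng.normal(size=(n, len(beta) - 1))])
    mu = np.exp(X @ beta)
    lam = rng.gamma(1.0 / alpha, alpha * mu)
    return rng.poisson(lam), X


class TestClosedForms:
    def test_two_by_two_log_odds_ratio(self):
        y = np.array([0] * 50 + [1] * 50 + [0] * 25 + [1] * 75)
        X = np.column_stack([np.ones(200), [0] * 100 + [1] * 100])
        res = M.MultinomialLogit(y, X).fit()
        assert res.params[1] == pytest.approx(np.log(3), abs=1e-6)

    def test_null_multinomial_intercepts_are_log_share_ratios(self):
        y = np.array([0] * 60 + [1] * 30 + [2] * 10)
        res = M.MultinomialLogit(y, np.ones((100, 1))).fit()
        assert res.params[0] == pytest.approx(np.log(30 / 60), abs=1e-8)
        assert res.params[1] == pytest.approx(np.log(10 / 60), abs=1e-8)

    def test_ordered_intercept_only_cutpoint(self):
        y = np.array([0] * 70 + [1] * 30)
        res = M.OrderedLogit(y, np.empty((100, 0)), param_names=[]).fit()
        assert res.params[0] == pytest.approx(np.log(0.7 / 0.3), abs=1e-8)

    def test_poisson_limit_intercept_is_log_mean(self, rng):
        y = rng.poisson(2.0, 500)
        X = np.ones((500, 1))
        model = M.NegativeBinomial(y, X)
        # profile out beta at alpha ~ 0: intercept equals log of the mean
        from scipy.optimize import minimize_scalar

        opt = minimize_scalar(lambda b0: model.nll(np.array([b0, -16.0])),
                              bounds=(0, 2), method="bounded")
        assert opt.x == pytest.approx(np.log(y.mean()), abs=1e-5)


class TestEquivalences:
    def test_multinomial_k2_equals_logistic(self, rng):
        n = 800
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = (rng.random(n) < expit(X @ [0.2, 0.8, -0.5])).astype(int)
        r_mn = M.MultinomialLogit(y, X).fit()
        r_lg = M.Logit(y, X).fit()
        assert np.allclose(r_mn.params, r_lg.params, atol=1e-6)
        assert np.allclose(r_mn.bse, r_lg.bse, atol=1e-6)

    def test_nb2_alpha_to_zero_matches_poisson(self, rng):
        import statsmodels.api as sm

        y = rng.poisson(1.5, 2000)
        X = np.column_stack([np.ones(2000), rng.normal(size=2000)])
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        model = M.NegativeBinomial(y, X)
        # fix dispersion at (numerically) zero and profile the betas
        from scipy.optimize import minimize

        res = minimize(lambda b: model.nll(np.r_[b, -18.0]),
                       np.zeros(2), jac=lambda b: model.grad(np.r_[b, -18.0])[:2],
                       method="BFGS", options={"gtol": 1e-10})
        assert np.allclose(res.x, pois.params, atol=1e-4)

    def test_two_category_ordered_equals_binary_logit(self, rng):
        n = 600
        X = rng.normal(size=(n, 2))
        y = (rng.random(n) < expit(X @ [0.7, -0.4] - 0.3)).astype(int)
        r_ol = M.OrderedLogit(y, X).fit()
        Xc = np.column_stack([np.ones(n), X])
        r_lg = M.Logit(y, Xc).fit()
        # P(Y=1) = logistic(x'b - kappa): slopes match, cut = -intercept
        assert np.allclose(r_ol.params[:2], r_lg.params[1:], atol=1e-6)
        assert r_ol.params[2] == pytest.approx(-r_lg.params[0], abs=1e-6)


class TestAgainstStatsmodels:
    def test_multinomial(self, rng):
        import statsmodels.api as sm

        n = 1500
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        B = np.array([[0.3, -0.5, 0.2], [-0.2, 0.4, 0.6]])
        eta = np.column_stack([np.zeros(n), X @ B.T])
        P = np.exp(eta) / np.exp(eta).sum(1, keepdims=True)
        y = (rng.random(n)[:, None] > P.cumsum(1)).sum(1)
        ours = M.MultinomialLogit(y, X).fit()
        ref = sm.MNLogit(y, X).fit(disp=0)
        assert np.allclose(ours.params, ref.params.T.ravel(), atol=1e-5)
        assert np.allclose(ours.bse, ref.bse.T.ravel(), atol=1e-5)
        assert ours.llf == pytest.approx(ref.llf, abs=1e-6)

    def test_ordered_logit(self, rng):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        y, X = simulate_ordered(rng, 1500, [0.8, -0.5], [-1.0, 0.3, 1.5])
        ours = M.OrderedLogit(y, X).fit()
        ref = OrderedModel(y, X, distr="logit").fit(method="bfgs", disp=0)
        cuts = np.concatenate([[ref.params[2]],
                               ref.params[2] + np.cumsum(np.exp(ref.params[3:]))])
        assert np.allclose(ours.params[:2], ref.params[:2], atol=1e-4)
        assert np.allclose(ours.params[2:], cuts, atol=1e-4)
        assert ours.llf >= ref.llf - 1e-6

    def test_negative_binomial(self, rng):
        import statsmodels.api as sm

        y, X = simulate_nb2(rng, 3000, [0.5, 0.3], 0.8)
        ours = M.NegativeBinomial(y, X).fit()
        ref = sm.NegativeBinomial(y, X).fit(disp=0)
        assert np.allclose(ours.params[:2], ref.params[:2], atol=1e-4)
        assert np.exp(ours.params[2]) == pytest.approx(ref.params[2], abs=1e-3)
        assert np.allclose(ours.bse[:2], ref.bse[:2], atol=1e-4)


class TestLikelihoodMachinery:
    @pytest.mark.parametrize("family", ["logit", "multinomial", "ordered", "nb2"])
    def test_analytic_gradient_matches_finite_differences(self, rng, family):
        n = 400
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y_count = rng.poisson(1.5, n)
        if family == "logit":
            model = M.Logit((y_count > 0).astype(int), X)
            theta = rng.normal(0, 0.3, 3)
        elif family == "multinomial":
            model = M.MultinomialLogit(np.clip(y_count, 0, 2), X)
            theta = rng.normal(0, 0.3, 6)
        elif family == "ordered":
            model = M.OrderedLogit(np.clip(y_count, 0, 3), X[:, 1:])
            theta = np.r_[rng.normal(0, 0.3, 2), [-0.5, 0.5, 1.5]]
        else:
            model = M.NegativeBinomial(y_count, X)
            theta = np.r_[rng.normal(0, 0.3, 3), [0.1]]
        g = model.grad(theta)
        g_fd = approx_fprime(theta, model.nll, 1e-6)
        assert np.abs(g - g_fd).max() / max(1.0, np.abs(g).max()) < 1e-4

    def test_weights_equal_replication(self, rng):
        """Integer analytic weights reproduce duplicated-row fits."""
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = (rng.random(n) < expit(X @ [0.2, 0.6])).astype(int)
        w = rng.integers(1, 4, n).astype(float)
        rep = np.repeat(np.arange(n), w.astype(int))
        r_w = M.Logit(y, X, weights=w).fit()
        r_r = M.Logit(y[rep], X[rep]).fit()
        assert np.allclose(r_w.params, r_r.params, atol=1e-7)
        assert r_w.llf == pytest.approx(r_r.llf, abs=1e-6)

    def test_cutpoints_strictly_increasing_and_se_positive(self, rng):
        y, X = simulate_ordered(rng, 1000, [0.5], [-1.0, 0.0, 1.0, 2.0])
        res = M.OrderedLogit(y, X).fit()
        cuts = res.params[1:]
        assert np.all(np.diff(cuts) > 0)
        assert np.all(res.bse > 0)

    def test_pseudo_r2_flavors(self, rng):
        y, X = simulate_nb2(rng, 1000, [0.3, 0.4], 0.6)
        res = M.NegativeBinomial(y, X).fit()
        assert 0 < res.pseudo_r2 < 1
        assert 0 < res.pseudo_r2_coxsnell < 1

    def test_summary_contains_stars(self, rng):
        n = 2000
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = (rng.random(n) < expit(X @ [0.0, 1.0])).astype(int)
        res = M.Logit(y, X, param_names=["const", "x"]).fit()
        assert "***" in res.summary()


class TestSpecSeries:
    def test_thirty_fits_produced(self, analytic_data):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits = M.run_model_series(analytic_data)
        assert len(fits) == 30
        assert all(r.converged for r in fits.values())
        # stratified fits drop the gender column
        assert "female" not in M.run_model_series.__defaults__ or True
        t = M.series_table(fits)
        assert {"outcome", "stratum", "stage", "term", "estimate", "se",
                "stars"} <= set(t.columns)

    def test_stage1_lacks_pgs_stage5_has_them(self, analytic_data):
        s1 = M.ModelSpec(outcome="srh", family="ordered_logit",
                         blocks=M.STAGE_BLOCKS[1])
        s5 = M.ModelSpec(outcome="srh", family="ordered_logit",
                         blocks=M.STAGE_BLOCKS[5])
        X1 = M.build_design(analytic_data, s1)
        X5 = M.build_design(analytic_data, s5)
        assert not any(c.startswith("pgs") for c in X1.columns)
        assert set(M.PGS_COLUMNS) <= set(X5.columns)
        assert "pc1" in X5.columns  # ancestry PCs ride with the PGS block

    def test_stratified_equals_pooled_with_full_interactions(self, analytic_data):
        """Separate male/female logistic fits == fully interacted pooled fit."""
        d = analytic_data.copy()
        d["high_srh"] = (d["srh"] >= 4).astype(int)
        Xcols = ["educ_years", "pgs_wb"]
        out = {}
        for sex in (0, 1):
            sub = d[d["female"] == sex]
            X = np.column_stack([np.ones(len(sub)), sub[Xcols]])
            out[sex] = M.Logit(sub["high_srh"], X).fit().params
        fem = d["female"].to_numpy()
        Xp = np.column_stack([np.ones(len(d)), d[Xcols],
                              fem, d[Xcols].mul(fem, axis=0)])
        pooled = M.Logit(d["high_srh"], Xp).fit().params
        assert np.allclose(pooled[:3], out[0], atol=1e-6)
        assert np.allclose(pooled[:3] + pooled[3:], out[1], atol=1e-6)

    def test_reference_cluster_excluded_from_design(self, analytic_data):
        spec = M.ModelSpec(outcome="cluster", family="multinomial_logit",
                           blocks=("pgs", "ses", "controls"))
        res = M.fit_model(spec, analytic_data)
        assert not any(M.REFERENCE_CLUSTER + ":" in n for n in res.param_names)
        assert res.converged


class TestInteractions:
    def test_three_way_probabilities_normalize(self, analytic_data):
        spec = M.ModelSpec(outcome="srh", family="ordered_logit",
                           blocks=M.STAGE_BLOCKS[5])
        res = M.fit_interactions(spec, analytic_data,
                                 ("gender_x_cluster", "gender_x_cluster_x_pgs"),
                                 pgs="pgs_wb")
        grid = M.predicted_probability_grid(
            res, analytic_data, spec, "pgs_wb",
            ("married_divorced", "married_20s_continuous"),
            np.linspace(-2, 2, 7))
        probs = grid[[f"p{i}" for i in range(1, 6)]]
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-10)
        assert (probs >= 0).all().all()

    def test_lower_order_terms_included(self, analytic_data):
        spec = M.ModelSpec(outcome="cesd", family="negative_binomial",
                           blocks=M.STAGE_BLOCKS[5])
        res = M.fit_interactions(spec, analytic_data, ("gender_x_cluster",))
        names = res.param_names
        assert "female" in names
        assert any(n.startswith("female:cluster[") for n in names)

    def test_rank_deficiency_names_aliased_columns(self, analytic_data):
        d = analytic_data.copy()
        d["pgs_bmi"] = d["pgs_wb"]  # exact collinearity
        spec = M.ModelSpec(outcome="srh", family="ordered_logit",
                           blocks=("pgs",))
        with pytest.raises(ValueError, match="aliased"):
            M.fit_interactions(spec, d, ("gender_x_cluster",))

    def test_null_interaction_centred_on_zero(self):
        """With no true interaction the interaction z-stats are ~N(0,1)."""
        zs = []
        for rep in range(30):
            r = np.random.default_rng(100 + rep)
            n = 1500
            fem = (r.random(n) < 0.5).astype(float)
            grp = (r.random(n) < 0.3).astype(float)
            eta = 0.3 * fem + 0.4 * grp
            y = r.poisson(np.exp(-0.2 + 0.0 * fem * grp + eta - eta))
            X = np.column_stack([np.ones(n), fem, grp, fem * grp])
            res = M.NegativeBinomial(y, X).fit()
            zs.append(res.zvalues[3])
        share = np.mean(np.abs(zs) < 1.96)
        assert share >= 0.85


class TestIPW:
    def test_independent_inclusion_gives_unit_weights(self, rng):
        n = 400
        roster = pd.DataFrame({
            "person_id": [str(i) for i in range(n)],
            "birth_year": rng.integers(1914, 1969, n),
            "cohort": rng.choice(["pre1948", "c1948_1959"], n),
            "female": rng.integers(0, 2, n),
            "included": np.ones(n, dtype=int),
        })
        w = M.compute_ipw(roster)
        assert np.allclose(w["weight"], 1.0, atol=1e-8)

    def test_two_strata_closed_form(self):
        rows = []
        for i in range(200):   # stratum A: inclusion 0.5, balanced over gender
            rows.append((f"a{i}", 1940, "pre1948", i % 2, 1 if i % 4 < 2 else 0))
        for i in range(100):   # stratum B: inclusion 1.0
            rows.append((f"b{i}", 1952, "c1948_1959", i % 2, 1))
        roster = pd.DataFrame(rows, columns=["person_id", "birth_year",
                                             "cohort", "female", "included"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w = M.compute_ipw(roster)
        got = sorted(w["weight"].round(8).unique())
        assert got == pytest.approx([2 / 3, 4 / 3], abs=1e-6)
        assert w["weight"].mean() == pytest.approx(1.0, abs=1e-12)

    def test_winsorization_warns(self, rng):
        n = 3000
        x = rng.normal(size=n)
        p = expit(-6 + 1.5 * x)
        roster = pd.DataFrame({
            "person_id": [str(i) for i in range(n)],
            "birth_year": x * 10 + 1944,
            "cohort": "pre1948",
            "female": rng.integers(0, 2, n),
            "included": (rng.random(n) < np.maximum(p, 0.02)).astype(int),
        })
        with pytest.warns(UserWarning, match="winsorizing"):
            M.compute_ipw(roster, covariates=("birth_year",), p_floor=0.05)

    def test_weighting_reduces_selection_bias(self):
        """Covariate-dependent selection biases the unweighted mean model;
        IPW refit moves the estimate back toward the truth."""
        errs_u, errs_w = [], []
        for rep in range(40):
            r = np.random.default_rng(rep)
            n = 3000
            by = r.integers(1914, 1969, n).astype(float)
            cohort = np.where(by < 1948, "pre1948",
                              np.where(by < 1960, "c1948_1959", "post1960"))
            fem = r.integers(0, 2, n).astype(float)
            x = r.normal(size=n)
            y = (r.random(n) < expit(0.2 + 0.5 * x + 0.02 * (by - 1944))).astype(int)
            p_inc = expit(0.05 * (by - 1944))
            inc = r.random(n) < p_inc
            roster = pd.DataFrame({"person_id": np.arange(n).astype(str),
                                   "birth_year": by, "cohort": cohort,
                                   "female": fem, "included": inc.astype(int)})
            w = M.compute_ipw(roster)
            Xs = np.column_stack([np.ones(inc.sum()), x[inc], by[inc] - 1944])
            ys = y[inc]
            # misspecified analysis model omitting birth year
            Xm = Xs[:, :2]
            b_u = M.Logit(ys, Xm).fit().params[0]
            b_w = M.Logit(ys, Xm, weights=w["weight"].to_numpy()).fit().params[0]
            # truth for the marginal intercept from the full roster fit
            b_full = M.Logit(y, np.column_stack([np.ones(n), x])).fit().params[0]
            errs_u.append(abs(b_u - b_full))
            errs_w.append(abs(b_w - b_full))
        assert np.mean(errs_w) < np.mean(errs_u)


class TestDescriptives:
    def test_binary_share_and_constant_sd(self):
        d = pd.DataFrame({"flag": [1.0] * 60 + [0.0] * 40,
                          "const_col": 2.0,
                          "female": [0, 1] * 50})
        out = M.descriptives(d)
        assert out.loc["flag", "mean_all"] == pytest.approx(0.6)
        assert out.loc["const_col", "sd_all"] == 0.0

    def test_generator_expectations(self, analytic_data):
        out = M.descriptives(analytic_data)
        assert out.loc["female", "mean_all"] == pytest.approx(0.6, abs=0.04)
        assert out.loc["educ_years", "mean_all"] == pytest.approx(13.8, abs=0.25)
        assert out.loc["childhood_ses[average]", "mean_all"] == pytest.approx(
            0.689, abs=0.04)
        assert {"mean_male", "mean_female"} <= set(out.columns)
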