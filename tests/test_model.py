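import numpy as np
import pandas as pd
import pytest
from scipy.special import logit, logsumexp

from dlnmm.families import loglik_parts
from dlnmm.model import DLNMCountModel, build_design, seasonal_dummies
from dlnmm.simulate import (
    ExposureParams,
    SimConfig,
    default_crossbasis_specs,
    simulate_exposures,
)


class TestDesign:
    def test_column_count_for_four_exposures(self, rng):
        # intercept + 4 cross-bases (3x3) + 51 seasonal dummies = 88
        cfg = SimConfig(n_subregions=2, n_weeks=120, seed=1)
        exposures = simulate_exposures(cfg)
        specs = default_crossbasis_specs(
            exposures, max_lags={n: 6 for n in ("temperature", "precipitation",
                                                "humidity", "aod")})
        counts = exposures[exposures["week"] >= 6][["subregion", "week"]].copy()
        counts["count"] = 1
        counts["population"] = 1000.0
        info = build_design(counts, exposures, specs=specs)
        assert info.X.shape[1] == 1 + 4 * 9 + 51
        assert info.column_names[0] == "intercept"
        assert np.allclose(info.offset, np.log(1000.0))
        assert len(info.cb_slices) == 4

    def test_seasonal_reference_coding(self):
        D, names = seasonal_dummies(np.arange(104))
        assert D.shape == (104, 51)
        # week 0 (reference season) has an all-zero row
        assert D[0].sum() == 0 and D[52].sum() == 0
        assert D[1, 0] == 1 and names[0] == "season_1"
        # all weeks in the reference season: block of zeros
        D0, _ = seasonal_dummies(np.zeros(10, dtype=int))
        assert not D0.any()

    def test_row_order_insensitive(self, small_panel):
        counts = small_panel["counts"]
        shuffled = counts.sample(frac=1.0, random_state=0)
        a = build_design(counts, small_panel["exposures"], small_panel["specs"])
        b = build_design(shuffled, small_panel["exposures"], small_panel["specs"])
        assert np.array_equal(a.X, b.X)
        assert np.array_equal(a.y, b.y)

    def test_misaligned_keys_raise(self, small_panel):
        counts = small_panel["counts"].copy()
        exposures = small_panel["exposures"]
        truncated = exposures[exposures["week"] < counts["week"].max() - 10]
        with pytest.raises(ValueError, match="beyond"):
            build_design(counts, truncated, small_panel["specs"])
        gappy = counts[counts["week"] != 30]
        with pytest.raises(ValueError, match="contiguous"):
            build_design(gappy, exposures, small_panel["specs"])


class TestFitting:
    def test_poisson_intercept_only_closed_form(self, rng):
        y = rng.poisson(4.2, 300)
        res = DLNMCountModel(y, np.ones((300, 1)), family="poisson").fit()
        assert res.beta[0] == pytest.approx(np.log(y.mean()), abs=1e-8)

    def test_likelihood_nesting_across_families(self, rng):
        mu = np.exp(1.0 + 0.3 * rng.normal(size=600))
        y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
        y[rng.random(600) < 0.1] = 0
        X = np.ones((600, 1))
        ll = {f: DLNMCountModel(y, X, family=f).fit(compute_vcov=False).llf
              for f in ("poisson", "negbin", "zinb")}
        assert ll["zinb"] >= ll["negbin"] - 1e-6
        assert ll["negbin"] >= ll["poisson"] - 1e-6

    def test_quadrature_marginal_against_monte_carlo(self, rng):
        """Adaptive GH integral vs brute-force MC integration at fixed params."""
        n_g, G = 40, 3
        X = np.column_stack([np.ones(n_g * G), rng.normal(size=(n_g * G, 2))])
        beta = np.array([1.0, 0.3, -0.2])
        sigma, kappa, pi = 0.4, 2.0, 0.1
        groups = np.repeat(np.arange(G), n_g)
        b = rng.normal(0, sigma, G)
        mu = np.exp(X @ beta + b[groups])
        y = rng.negative_binomial(kappa, kappa / (kappa + mu)).astype(float)
        y[rng.random(y.size) < pi] = 0
        model = DLNMCountModel(y, X, groups=groups, family="zinb")
        params = np.concatenate([beta, [np.log(kappa), logit(pi), np.log(sigma)]])
        ll_gh = model.loglike(params)

        draws = rng.normal(0, sigma, 200_000)
        ll_mc = 0.0
        for g in range(G):
            sl = slice(g * n_g, (g + 1) * n_g)
            lp = loglik_parts(y[sl][:, None], (X[sl] @ beta)[:, None]
                              + draws[None, :], kappa, pi)["logpmf"].sum(0)
            ll_mc += logsumexp(lp) - np.log(draws.size)
        # agreement to 3 significant digits of the total log-likelihood
        assert ll_gh == pytest.approx(ll_mc, abs=5e-2)

    def test_quadrature_node_count_stability(self, rng):
        n_g, G = 150, 4
        X = np.column_stack([np.ones(n_g * G), rng.normal(size=(n_g * G, 1))])
        beta = np.array([1.2, 0.3])
        groups = np.repeat(np.arange(G), n_g)
        mu = np.exp(X @ beta + rng.normal(0, 0.3, G)[groups])
        y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
        params = np.concatenate([beta, [np.log(2.0), np.log(0.3)]])
        lls = [DLNMCountModel(y, X, groups=groups, family="negbin",
                              n_quad=q).loglike(params) for q in (7, 15, 31)]
        assert max(lls) - min(lls) < 1e-4

    def test_analytic_score_matches_finite_differences(self, rng):
        n_g, G = 60, 3
        X = np.column_stack([np.ones(n_g * G), rng.normal(size=(n_g * G, 2))])
        groups = np.repeat(np.arange(G), n_g)
        mu = np.exp(1.0 + 0.2 * X[:, 1])
        y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu)).astype(float)
        y[rng.random(y.size) < 0.1] = 0
        model = DLNMCountModel(y, X, groups=groups, family="zinb")
        params = np.array([0.9, 0.15, -0.1, np.log(1.8), logit(0.12),
                           np.log(0.25)])
        _, score = model.loglike_and_score(params)
        h = 1e-6
        for j in range(params.size):
            up, dn = params.copy(), params.copy()
            up[j] += h
            dn[j] -= h
            fd = (model.loglike(up) - model.loglike(dn)) / (2 * h)
            assert score[j] == pytest.approx(fd, rel=1e-4, abs=1e-4)

    def test_vcov_symmetric_with_nonnegative_diagonal(self, small_fit):
        V = small_fit.vcov
        assert np.allclose(V, V.T, atol=1e-10)
        assert np.diag(V).min() >= 0

    def test_fit_is_deterministic(self, small_panel):
        kw = dict(specs=small_panel["specs"], family="negbin",
                  random_intercept=True)
        r1 = DLNMCountModel.from_panels(small_panel["counts"],
                                        small_panel["exposures"], **kw).fit()
        r2 = DLNMCountModel.from_panels(small_panel["counts"],
                                        small_panel["exposures"], **kw).fit()
        assert np.array_equal(r1.params, r2.params)
        assert r1.llf == r2.llf

    def test_single_group_random_intercept_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            DLNMCountModel(np.array([1, 2]), np.ones((2, 1)),
                           groups=np.zeros(2), family="poisson")

    def test_input_validation(self):
        with pytest.raises(ValueError, match="family"):
            DLNMCountModel(np.array([1]), np.ones((1, 1)), family="gamma")
        with pytest.raises(ValueError, match="nonnegative"):
            DLNMCountModel(np.array([-1]), np.ones((1, 1)))


class TestDiagnostics:
    def test_residuals_vanish_when_fit_is_exact(self):
        # constant counts: the intercept-only Poisson MLE fits exactly
        y = np.full(150, 6)
        res = DLNMCountModel(y, np.ones((150, 1)), family="poisson").fit()
        for kind in ("raw", "pearson", "deviance"):
            assert np.allclose(res.resid(kind), 0.0, atol=1e-6)

    def test_raw_residuals_sum_to_zero_for_poisson_mle(self, rng):
        y = rng.poisson(3.0, 400)
        res = DLNMCountModel(y, np.ones((400, 1)), family="poisson").fit()
        assert abs(res.resid("raw").sum()) < 1e-6

    def test_pearson_residual_variance_near_one_when_well_specified(self, rng):
        mu = np.exp(1.5 + 0.3 * rng.normal(size=3000))
        y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
        X = np.column_stack([np.ones(3000), np.log(mu) - 1.5])
        res = DLNMCountModel(y, X, family="negbin").fit()
        v = res.resid("pearson").var()
        assert 0.85 < v < 1.15

    def test_overdispersion_flags_nb_data_fitted_as_poisson(self, rng):
        mu = np.full(800, 5.0)
        y = rng.negative_binomial(1.0, 1.0 / (1.0 + mu))  # kappa = 1
        res = DLNMCountModel(y, np.ones((800, 1)), family="poisson").fit()
        assert res.overdispersion_ratio > 1.5
        assert res.recommends_negbin

    def test_overdispersion_near_one_under_poisson_truth(self, rng):
        y = rng.poisson(5.0, 2000)
        res = DLNMCountModel(y, np.ones((2000, 1)), family="poisson").fit()
        assert res.overdispersion_ratio == pytest.approx(1.0, abs=0.15)

    def test_overdispersion_requires_poisson_family(self, small_fit):
        with pytest.raises(ValueError, match="Poisson"):
            _ = small_fit.overdispersion_ratio

    def test_unknown_residual_type(self, small_fit):
        with pytest.raises(ValueError, match="residual"):
            small_fit.resid("studentized")

    def test_summary_and_serialization(self, small_fit):
        text = small_fit.summary()
        assert "ZINB" in text and "sigma_b" in text
        d = small_fit.to_dict()
        assert set(d) >= {"family", "params", "llf", "aic", "bic", "vcov"}
        assert "temperature" in d["crossbasis_specs"]

    def test_information_criteria_formulas(self, small_fit):
        q = small_fit.df_model
        n = small_fit.nobs
        assert small_fit.aic == pytest.approx(-2 * small_fit.llf + 2 * q)
        assert small_fit.bic == pytest.approx(-2 * small_fit.llf + q * np.log(n))
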