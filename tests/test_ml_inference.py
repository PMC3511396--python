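"""Marginal likelihoods (closed-form and AGQ), fitting, model selection."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import multivariate_normal, norm

from n2o_uncertainty.ml_inference import (
    FitResult,
    as_pubdata,
    default_init,
    fit_ml,
    loglik_linear_mixed,
    loglik_nonlinear_mixed,
    model_selection_table,
)
from n2o_uncertainty.model_suite import ParamSet, get_model, mean_response
from n2o_uncertainty.synthetic_data import DesignConfig, generate_dataset


def _dense_grid_loglik(spec, params, x, y, n_grid=100_001, half_width=8.0):
    """Brute-force 1-D marginal likelihood by trapezoid integration over the
    single random effect — the quadrature oracle."""
    sd = params.sigma0 if spec.random_intercept else params.sigma1
    grid = np.linspace(-half_width * sd, half_width * sd, n_grid)
    if spec.random_intercept:
        eta = params.mu0 + grid[:, None] + params.mu1 * x[None, :]
    else:
        eta = params.mu0 + (params.mu1 + grid[:, None]) * x[None, :]
    mean = eta if spec.linear else np.exp(eta)
    dens = np.prod(norm.pdf(y[None, :], mean, params.tau), axis=1)
    dens *= norm.pdf(grid, 0.0, sd)
    return math.log(np.trapezoid(dens, grid))


class TestLinearLoglik:
    def test_standard_normal_single_observation(self):
        df = pd.DataFrame({"publication_id": ["a"], "n_rate_kg_ha": [0.0],
                           "n2o_kg_n_ha_yr": [0.0]})
        spec = get_model("L-0-F")
        ll = loglik_linear_mixed(spec, ParamSet(mu0=0.0, tau=1.0), df)
        assert ll == pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_independence_limit(self, multi_pub_frame):
        spec = get_model("L-N-FF")
        params = ParamSet(mu0=1.0, mu1=0.01, tau=2.0)
        ll = loglik_linear_mixed(spec, params, multi_pub_frame)
        x = multi_pub_frame["n_rate_kg_ha"].to_numpy()
        y = multi_pub_frame["n2o_kg_n_ha_yr"].to_numpy()
        expected = norm.logpdf(y, 1.0 + 0.01 * x, 2.0).sum()
        assert ll == pytest.approx(expected)

    @pytest.mark.parametrize("name", ["L-0-R", "L-N-RF", "L-N-FR", "L-N-RR"])
    def test_matches_multivariate_normal_oracle(self, name, multi_pub_frame):
        spec = get_model(name)
        params = ParamSet(
            mu0=1.0,
            mu1=0.01 if spec.uses_N else 0.0,
            sigma0=0.7 if spec.random_intercept else 0.0,
            sigma1=0.012 if spec.random_slope else 0.0,
            tau=1.5,
        )
        ll = loglik_linear_mixed(spec, params, multi_pub_frame)
        expected = 0.0
        for _, sub in multi_pub_frame.groupby("publication_id"):
            x = sub["n_rate_kg_ha"].to_numpy()
            y = sub["n2o_kg_n_ha_yr"].to_numpy()
            cov = params.tau**2 * np.eye(len(x))
            if spec.random_intercept:
                cov = cov + params.sigma0**2
            if spec.random_slope:
                cov = cov + params.sigma1**2 * np.outer(x, x)
            mu = params.mu0 + (params.mu1 if spec.uses_N else 0.0) * x
            expected += multivariate_normal.logpdf(y, mu, cov)
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_random_intercept_matches_quadrature(self, single_pub_frame):
        """Marginalizing the intercept numerically reproduces the closed form."""
        spec = get_model("L-N-RF")
        params = ParamSet(mu0=1.0, mu1=0.008, sigma0=0.6, tau=1.2)
        x = single_pub_frame["n_rate_kg_ha"].to_numpy()
        y = single_pub_frame["n2o_kg_n_ha_yr"].to_numpy()

        def integrand(a0):
            return np.prod(
                norm.pdf(y, params.mu0 + a0 + params.mu1 * x, params.tau)
            ) * norm.pdf(a0, 0, params.sigma0)

        oracle, _ = quad(integrand, -8 * 0.6, 8 * 0.6, limit=200)
        ll = loglik_linear_mixed(spec, params, single_pub_frame)
        assert ll == pytest.approx(math.log(oracle), abs=1e-6)

    def test_singular_covariance_rejected(self, single_pub_frame):
        with pytest.raises(ValueError, match="singular"):
            loglik_linear_mixed(
                get_model("L-N-FF"), ParamSet(mu0=1.0, mu1=0.01, tau=0.0),
                single_pub_frame,
            )

    def test_invariant_to_relabeling_and_order(self, multi_pub_frame):
        spec = get_model("L-N-RR")
        params = ParamSet(mu0=1.0, mu1=0.01, sigma0=0.5, sigma1=0.01, tau=1.5)
        base = loglik_linear_mixed(spec, params, multi_pub_frame)
        shuffled = multi_pub_frame.sample(frac=1.0, random_state=4)
        relabeled = shuffled.assign(
            publication_id=shuffled["publication_id"].map(lambda s: "x" + s)
        )
        assert loglik_linear_mixed(spec, params, relabeled) == pytest.approx(base)


class TestNonlinearLoglik:
    PARAMS_RI = ParamSet(mu0=0.2, mu1=0.004, sigma0=0.7, tau=1.0)

    def test_no_random_effects_is_plain_gaussian(self, multi_pub_frame):
        spec = get_model("NL-N-FF")
        params = ParamSet(mu0=0.2, mu1=0.004, tau=1.5)
        x = multi_pub_frame["n_rate_kg_ha"].to_numpy()
        y = multi_pub_frame["n2o_kg_n_ha_yr"].to_numpy()
        expected = norm.logpdf(y, np.exp(0.2 + 0.004 * x), 1.5).sum()
        for n_nodes in (1, 9):
            ll = loglik_nonlinear_mixed(spec, params, multi_pub_frame, n_nodes=n_nodes)
            assert ll == pytest.approx(expected)

    @pytest.mark.parametrize("name,params", [
        ("NL-N-RF", ParamSet(mu0=0.2, mu1=0.004, sigma0=0.7, tau=1.0)),
        ("NL-N-FR", ParamSet(mu0=0.2, mu1=0.004, sigma1=0.003, tau=1.0)),
    ])
    def test_agq_matches_dense_grid_oracle(self, name, params, single_pub_frame):
        spec = get_model(name)
        x = single_pub_frame["n_rate_kg_ha"].to_numpy()
        y = single_pub_frame["n2o_kg_n_ha_yr"].to_numpy()
        oracle = _dense_grid_loglik(spec, params, x, y)
        ll = loglik_nonlinear_mixed(spec, params, single_pub_frame, n_nodes=25)
        assert abs(ll - oracle) / abs(oracle) < 1e-5

    def test_node_count_converges_toward_oracle(self, single_pub_frame):
        spec = get_model("NL-N-RF")
        x = single_pub_frame["n_rate_kg_ha"].to_numpy()
        y = single_pub_frame["n2o_kg_n_ha_yr"].to_numpy()
        oracle = _dense_grid_loglik(spec, self.PARAMS_RI, x, y)
        errors = [
            abs(loglik_nonlinear_mixed(spec, self.PARAMS_RI, single_pub_frame,
                                       n_nodes=n) - oracle)
            for n in (3, 9, 15)
        ]
        assert errors[0] >= errors[1] >= errors[2]
        assert errors[2] < 1e-4

    def test_identity_link_reproduces_linear_closed_form(self, multi_pub_frame):
        """The AGQ machinery applied to an identity mean is exact for the
        linear mixed model (cross-implementation check)."""
        spec = get_model("L-N-RR")
        params = ParamSet(mu0=1.0, mu1=0.01, sigma0=0.6, sigma1=0.012, tau=1.5)
        closed = loglik_linear_mixed(spec, params, multi_pub_frame)
        agq = loglik_nonlinear_mixed(spec, params, multi_pub_frame, n_nodes=9,
                                     _link="identity")
        assert agq == pytest.approx(closed, abs=1e-6)

    def test_even_node_count_rejected(self, single_pub_frame):
        with pytest.raises(ValueError):
            loglik_nonlinear_mixed(get_model("NL-N-RF"), self.PARAMS_RI,
                                   single_pub_frame, n_nodes=4)

    def test_laplace_close_to_agq_on_two_random_effects(self, multi_pub_frame):
        spec = get_model("NL-N-RR")
        params = ParamSet(mu0=0.2, mu1=0.004, sigma0=0.5, sigma1=0.002, tau=1.2)
        laplace = loglik_nonlinear_mixed(spec, params, multi_pub_frame, n_nodes=1)
        agq = loglik_nonlinear_mixed(spec, params, multi_pub_frame, n_nodes=15)
        assert laplace == pytest.approx(agq, rel=5e-3)


class TestFitMl:
    def test_closed_form_matches_optimizer_for_fixed_linear(self, multi_pub_frame):
        spec = get_model("L-N-FF")
        fit = fit_ml(spec, multi_pub_frame)
        assert fit.optimizer_trace["method"] == "closed-form OLS"
        # the closed form is the global optimum of the generic objective
        ll_pert = loglik_linear_mixed(
            spec,
            ParamSet(mu0=fit.estimates.mu0 + 0.05, mu1=fit.estimates.mu1,
                     tau=fit.estimates.tau),
            multi_pub_frame,
        )
        assert fit.loglik >= ll_pert

    def test_information_criteria_identities(self, multi_pub_frame):
        fit = fit_ml(get_model("L-N-FF"), multi_pub_frame)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params, abs=1e-8)
        assert fit.bic == pytest.approx(
            -2 * fit.loglik + fit.n_params * math.log(fit.n_obs), abs=1e-8
        )
        assert fit.n_params == 3

    def test_loglik_maximal_at_truth_for_tiny_noise(self):
        spec = get_model("NL-N-FF")
        truth = ParamSet(mu0=0.2, mu1=0.004, tau=0.01)
        records, _ = generate_dataset(
            spec, truth, DesignConfig(n_publications=5, seed=8)
        )
        ll_truth = loglik_nonlinear_mixed(spec, truth, records)
        ll_pert = loglik_nonlinear_mixed(
            spec, ParamSet(mu0=0.25, mu1=0.004, tau=0.01), records
        )
        assert ll_truth >= ll_pert

    def test_intercept_only_recovery_within_3_se(self):
        truth = ParamSet(mu0=2.4, tau=4.26)
        records, _ = generate_dataset(
            get_model("L-0-F"), truth,
            DesignConfig(n_publications=165, doses_per_publication=3,
                         replicates_per_dose=2, seed=31),
        )
        fit = fit_ml(get_model("L-0-F"), records)
        assert fit.converged
        assert abs(fit.estimates.mu0 - 2.4) < 3 * fit.standard_errors["mu0"]

    def test_random_intercept_fit_matches_statsmodels(self):
        """Independent oracle: statsmodels MixedLM maximum likelihood."""
        import statsmodels.api as sm

        spec = get_model("L-N-RF")
        truth = ParamSet(mu0=0.99, mu1=0.0130, sigma0=1.5, tau=2.0)
        records, _ = generate_dataset(
            spec, truth,
            DesignConfig(n_publications=80, seed=17),
        )
        fit = fit_ml(spec, records)
        frame = as_pubdata(records)
        x = frame.all_x()
        y = frame.all_y()
        groups = np.repeat(
            np.arange(frame.n_publications),
            [len(v) for v in frame.y],
        )
        sm_fit = sm.MixedLM(y, np.column_stack([np.ones_like(x), x]), groups).fit(
            reml=False
        )
        assert fit.estimates.mu0 == pytest.approx(sm_fit.params[0], abs=1e-2)
        assert fit.estimates.mu1 == pytest.approx(sm_fit.params[1], rel=1e-2)
        assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-3)

    def test_nonconvergence_reported_not_raised(self, multi_pub_frame):
        fit = fit_ml(get_model("L-N-RR"), multi_pub_frame,
                     options={"maxiter": 1})
        assert isinstance(fit, FitResult)

    def test_random_effect_models_need_two_publications(self, single_pub_frame):
        with pytest.raises(ValueError, match="publications"):
            fit_ml(get_model("L-N-RR"), single_pub_frame)

    def test_fit_result_json_round_trip(self, multi_pub_frame, tmp_path):
        fit = fit_ml(get_model("L-N-FF"), multi_pub_frame)
        path = tmp_path / "fit.json"
        fit.to_json(path)
        loaded = FitResult.from_json(path)
        assert loaded.spec == fit.spec
        assert loaded.estimates == fit.estimates
        assert loaded.aic == pytest.approx(fit.aic)


class TestModelSelectionTable:
    @staticmethod
    def _fake_fit(name, aic, bic):
        spec = get_model(name)
        return FitResult(
            spec=spec, estimates=ParamSet(mu0=0.0, tau=1.0),
            standard_errors={}, loglik=0.0, n_obs=10, n_params=spec.n_params,
            aic=aic, bic=bic, converged=True,
        )

    def test_percentage_definition(self):
        fits = [self._fake_fit("L-N-FF", 100.0, 100.0),
                self._fake_fit("L-N-RR", 110.0, 110.0)]
        table = model_selection_table(fits).set_index("model")
        assert table.loc["L-N-FF", "pct_aic"] == 0.0
        assert table.loc["L-N-RR", "pct_aic"] == pytest.approx(10.0)

    def test_single_model_per_family_scores_zero(self):
        fits = [self._fake_fit("L-N-FF", 123.0, 130.0),
                self._fake_fit("NL-N-FF", 117.0, 121.0)]
        table = model_selection_table(fits)
        assert (table["pct_aic"] == 0.0).all()
        assert (table["pct_bic"] == 0.0).all()

    def test_percentages_are_within_family(self):
        fits = [
            self._fake_fit("NL-N-RR", 4482.7, 4507.1),
            self._fake_fit("NL-N-RF", 4553.9, 4573.5),
            self._fake_fit("L-N-RR", 4693.2, 4717.6),
            self._fake_fit("L-N-FR", 4698.0, 4717.5),
        ]
        table = model_selection_table(fits).set_index("model")
        assert table.loc["NL-N-RF", "pct_aic"] == pytest.approx(1.6, abs=0.05)
        assert table.loc["L-N-FR", "pct_aic"] == pytest.approx(0.1, abs=0.05)
        assert table.loc["L-N-RR", "pct_bic"] == pytest.approx(0.002, abs=0.005)

    def test_duplicate_names_rejected(self):
        fits = [self._fake_fit("L-N-FF", 1.0, 1.0)] * 2
        with pytest.raises(ValueError, match="duplicate"):
            model_selection_table(fits)


def test_default_init_is_finite_for_all_models(multi_pub_frame):
    for name in ("L-0-F", "L-N-RR", "NL-N-FF", "NL-N-RR"):
        init = default_init(get_model(name), multi_pub_frame)
        assert np.isfinite([init.mu0, init.mu1, init.tau]).all()
        assert init.tau > 0
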