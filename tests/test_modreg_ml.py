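import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from tobitkit import (
    ModRegCondition,
    ModRegParams,
    ModeratedRegression,
    TobitModeratedRegression,
    gen_modreg,
    tobit_regression_outcome_only,
)
from tobitkit.censoring import CensoredVariable, CensoringBounds, ModRegData
from tobitkit.modreg_ml import modreg_censored_loglik, wald_inference


def _data(y, x, z, y_bounds=None, x_bounds=None, z_bounds=None):
    unbounded = CensoringBounds()
    return ModRegData(
        y=CensoredVariable.from_observed(y, y_bounds or unbounded),
        x=CensoredVariable.from_observed(x, x_bounds or unbounded),
        z=CensoredVariable.from_observed(z, z_bounds or unbounded),
    )


class TestOutcomeOnly:
    def test_reduces_to_ols_without_censoring(self, uncensored_modreg_data):
        fit = tobit_regression_outcome_only(uncensored_modreg_data)
        ols = ModeratedRegression(uncensored_modreg_data).fit()
        assert fit.converged
        assert np.allclose(fit.params.beta, ols.params, atol=1e-6)
        n = uncensored_modreg_data.n
        resid_var_mle = ols.sigma2 * (n - 4) / n
        assert fit.params.sigma_e2 == pytest.approx(resid_var_mle, rel=1e-4)

    def test_ceiling_contribution_is_half_at_the_bound(self):
        # linear predictor equal to the ceiling: tail probability Phi(0)=0.5
        data = _data([1.0], [1.0], [0.0], y_bounds=CensoringBounds(ceiling=1.0))
        model = TobitModeratedRegression(data)
        ll = model.loglike_outcome_only(np.array([0.0, 1.0, 0.0, 0.0]), 1.0)
        assert ll == pytest.approx(np.log(0.5))

    def test_recovers_parameters_under_y_ceiling(self):
        rng = np.random.default_rng(10)
        n = 2000
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        y = x + z + 0.39 * x * z + rng.standard_normal(n)
        b = np.quantile(y, 0.8)
        data = _data(np.minimum(y, b), x, z, y_bounds=CensoringBounds(ceiling=b))
        fit = tobit_regression_outcome_only(data)
        assert fit.converged
        truth = np.array([0.0, 1.0, 1.0, 0.39])
        assert np.all(np.abs(fit.params.beta - truth) < 3 * fit.bse[:4])

    def test_requires_observed_predictors(self, scenario1_data):
        with pytest.raises(ValueError, match="fully observed"):
            tobit_regression_outcome_only(scenario1_data)


class TestCensoredLoglik:
    params = ModRegParams(
        beta=np.array([0.1, 1.0, 0.8, 0.39]),
        sigma_e2=0.9, mu_x=0.1, mu_z=-0.2,
        var_x=1.2, var_z=0.8, cov_xz=0.3,
    )

    def test_unbounded_factorises_exactly(self, rng):
        n = 40
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        y = rng.standard_normal(n)
        data = _data(y, x, z)
        p = self.params
        f_xz = multivariate_normal(
            [p.mu_x, p.mu_z],
            [[p.var_x, p.cov_xz], [p.cov_xz, p.var_z]],
        ).logpdf(np.column_stack([x, z]))
        m = p.beta[0] + p.beta[1] * x + p.beta[2] * z + p.beta[3] * x * z
        f_y = norm.logpdf(y, loc=m, scale=np.sqrt(p.sigma_e2))
        assert modreg_censored_loglik(p, data) == pytest.approx(
            float(np.sum(f_xz + f_y))
        )

    def test_censored_x_with_null_slopes_factorises(self):
        # with beta1 = beta3 = 0 the outcome carries no information about
        # x*, so the integral reduces to a conditional tail probability
        p = ModRegParams(
            beta=np.array([0.0, 0.0, 0.8, 0.0]),
            sigma_e2=1.0, mu_x=0.0, mu_z=0.0,
            var_x=1.0, var_z=1.0, cov_xz=0.3,
        )
        bX = 1.0
        z_val, y_val = 0.4, 0.7
        data = _data([y_val], [bX], [z_val],
                     x_bounds=CensoringBounds(ceiling=bX))
        mu_c = 0.3 * z_val
        sd_c = np.sqrt(1 - 0.09)
        expected = (
            norm.logpdf(z_val)
            + norm.logsf(bX, loc=mu_c, scale=sd_c)
            + norm.logpdf(y_val, loc=0.8 * z_val, scale=1.0)
        )
        assert modreg_censored_loglik(p, data) == pytest.approx(
            float(expected), abs=1e-8
        )

    def test_matches_monte_carlo_integration(self, rng):
        """Row likelihoods with censored predictors/moderators against
        brute-force Monte-Carlo integration over the censored regions."""
        p = self.params
        bX, bZ, bY = 0.9, 0.7, 1.1
        sig = np.sqrt(p.sigma_e2)
        n_mc = 10_000_000

        def mean_y(x, z):
            return (p.beta[0] + p.beta[1] * x + p.beta[2] * z
                    + p.beta[3] * x * z)

        def g_y(y_val, censored, m):
            return (norm.sf(bY, loc=m, scale=sig) if censored
                    else norm.pdf(y_val, loc=m, scale=sig))

        # pattern rows: (x, z, y, x_cens, z_cens, y_cens)
        rows = [
            (bX, 0.2, 0.3, True, False, False),
            (bX, 0.2, bY, True, False, True),
            (bX, bZ, 0.4, True, True, False),
            (bX, bZ, bY, True, True, True),
            (0.5, bZ, 0.3, False, True, False),
        ]
        for x_val, z_val, y_val, xc, zc, yc in rows:
            data = _data(
                [y_val], [x_val], [z_val],
                y_bounds=CensoringBounds(ceiling=bY),
                x_bounds=CensoringBounds(ceiling=bX),
                z_bounds=CensoringBounds(ceiling=bZ),
            )
            ll = modreg_censored_loglik(p, data, quadrature_nodes=60)
            if xc and zc:
                # E over the joint exogenous normal of the region indicator
                # times the outcome term
                xz = rng.multivariate_normal(
                    [p.mu_x, p.mu_z],
                    [[p.var_x, p.cov_xz], [p.cov_xz, p.var_z]],
                    size=n_mc, method="cholesky",
                )
                vals = ((xz[:, 0] >= bX) & (xz[:, 1] >= bZ)) * g_y(
                    y_val, yc, mean_y(xz[:, 0], xz[:, 1])
                )
            elif xc:
                # z fixed: density of z times E over x | z in the region
                cm = p.mu_x + p.cov_xz / p.var_z * (z_val - p.mu_z)
                cs = np.sqrt(p.var_x - p.cov_xz**2 / p.var_z)
                x_draws = cm + cs * rng.standard_normal(n_mc)
                vals = (
                    norm.pdf(z_val, loc=p.mu_z, scale=np.sqrt(p.var_z))
                    * (x_draws >= bX)
                    * g_y(y_val, yc, mean_y(x_draws, z_val))
                )
            else:  # z censored only
                cm = p.mu_z + p.cov_xz / p.var_x * (x_val - p.mu_x)
                cs = np.sqrt(p.var_z - p.cov_xz**2 / p.var_x)
                z_draws = cm + cs * rng.standard_normal(n_mc)
                vals = (
                    norm.pdf(x_val, loc=p.mu_x, scale=np.sqrt(p.var_x))
                    * (z_draws >= bZ)
                    * g_y(y_val, yc, mean_y(x_val, z_draws))
                )
            mc = float(np.mean(vals))
            mc_se = float(np.std(vals)) / np.sqrt(n_mc)
            assert abs(np.exp(ll) - mc) < 3 * mc_se

    def test_quadrature_node_doubling_is_stable(self, scenario1_data):
        model = TobitModeratedRegression(scenario1_data)
        p = model.start_params()
        l40 = model.loglike(p, nodes=40)
        l80 = model.loglike(p, nodes=80)
        assert l40 == pytest.approx(l80, abs=1e-6)

    def test_outcome_only_and_general_paths_agree(self):
        rng = np.random.default_rng(12)
        n = 150
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        y = np.minimum(x + z + rng.standard_normal(n), 1.0)
        data = _data(y, x, z, y_bounds=CensoringBounds(ceiling=1.0))
        model = TobitModeratedRegression(data)
        p = model.start_params()
        # the general path adds the exogenous density, a fixed offset
        f_xz = multivariate_normal(
            [p.mu_x, p.mu_z],
            [[p.var_x, p.cov_xz], [p.cov_xz, p.var_z]],
        ).logpdf(np.column_stack([x, z])).sum()
        general = model.loglike(p)
        outcome = model.loglike_outcome_only(p.beta, p.sigma_e2)
        assert general == pytest.approx(outcome + float(f_xz), abs=1e-8)


class TestFit:
    def test_cp0_equals_ols(self, uncensored_modreg_data):
        fit = TobitModeratedRegression(uncensored_modreg_data).fit()
        ols = ModeratedRegression(uncensored_modreg_data).fit()
        assert np.allclose(fit.params.beta, ols.params, atol=1e-6)

    def test_scenario2_recovery_at_large_n(self):
        data = gen_modreg(
            ModRegCondition(scenario="z_censored", beta3=0.39, rho=0.3,
                            cp=0.2, n=2000, seed=7)
        )
        fit = TobitModeratedRegression(data).fit()
        assert fit.converged
        truth = np.array([0.0, 1.0, 1.0, 0.39])
        assert np.all(np.abs(fit.params.beta - truth) < 3 * fit.bse[:4])

    def test_scenario1_recovery_at_large_n(self):
        data = gen_modreg(
            ModRegCondition(scenario="xy_censored", beta3=0.39, rho=0.3,
                            cp=0.2, n=2000, seed=8)
        )
        fit = TobitModeratedRegression(data).fit()
        assert fit.converged
        truth = np.array([0.0, 1.0, 1.0, 0.39])
        assert np.all(np.abs(fit.params.beta - truth) < 3 * fit.bse[:4])
        # exogenous distribution also recovered
        assert fit.params.mu_x == pytest.approx(0.0, abs=0.1)
        assert fit.params.exo_corr == pytest.approx(0.3, abs=0.07)


class TestWald:
    def test_normal_reference_quantiles(self, uncensored_modreg_data):
        fit = TobitModeratedRegression(uncensored_modreg_data).fit()
        tab = wald_inference(fit)
        est, se = tab["estimate"].to_numpy(), tab["se"].to_numpy()
        assert np.allclose(tab["stat"], est / se)
        assert np.allclose(tab["ci_lo"], est - 1.959964 * se, atol=1e-5)
        p_at_196 = 2 * norm.sf(1.96)
        row = tab.iloc[1]
        if abs(row["stat"]) > 1.96:
            assert row["p"] < p_at_196 + 1e-9

    def test_simple_slope_at_zero_is_main_effect(self, scenario1_data):
        fit = TobitModeratedRegression(scenario1_data).fit()
        est, se = fit.simple_slope(0.0)
        assert est == pytest.approx(fit.params.beta[1])
        assert se == pytest.approx(fit.bse[1])
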