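import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import multivariate_normal, norm

from tobitkit import (
    PairedCondition,
    PairedTTest,
    PairedTobitParams,
    TobitPairedTTest,
    factor_solution,
    gen_paired,
)
from tobitkit._bvn import bvn_cdf, rectangle_prob
from tobitkit.paired_ml import censored_paired_loglik, paired_tobit_ttest

from conftest import make_paired


class TestBvnCdf:
    def test_matches_scipy_mvn(self, rng):
        for _ in range(100):
            h, k = rng.normal(size=2) * 2.5
            rho = rng.uniform(-0.99, 0.99)
            ref = multivariate_normal(cov=[[1, rho], [rho, 1]]).cdf([h, k])
            assert bvn_cdf(h, k, rho) == pytest.approx(ref, abs=1e-9)

    @pytest.mark.parametrize("h,k,rho", [(0, 1.3, 0.5), (0, 0, 0.7), (0, -1, 0.3)])
    def test_zero_arguments(self, h, k, rho):
        ref = multivariate_normal(cov=[[1, rho], [rho, 1]]).cdf([h, k])
        assert bvn_cdf(h, k, rho) == pytest.approx(ref, abs=1e-9)

    def test_quadrant_partition_sums_to_one(self, rng):
        # the nine floor/interior/ceiling cells of the plane carry total mass 1
        for _ in range(20):
            rho = rng.uniform(-0.95, 0.95)
            a1, b1 = sorted(rng.normal(size=2) * 1.5)
            a2, b2 = sorted(rng.normal(size=2) * 1.5)
            cuts1 = [-np.inf, a1, b1, np.inf]
            cuts2 = [-np.inf, a2, b2, np.inf]
            total = sum(
                rectangle_prob(cuts1[i], cuts1[i + 1], cuts2[j], cuts2[j + 1], rho)
                for i in range(3)
                for j in range(3)
            )
            assert total == pytest.approx(1.0, abs=1e-10)


class TestCensoredPairedLoglik:
    std = PairedTobitParams(0.0, 0.0, 1.0, 1.0, 0.0)

    def test_both_at_ceiling_independent_quadrant(self):
        # independent standard normals censored at 0: P(Y1>=0)P(Y2>=0) = 1/4
        sample = make_paired([0.0], [0.0], ceiling=0.0)
        assert censored_paired_loglik(self.std, sample) == pytest.approx(
            np.log(0.25), abs=1e-10
        )

    def test_one_censored_one_interior(self):
        sample = make_paired([-1.0], [0.0], ceiling=0.0)
        expected = np.log(norm.pdf(-1.0) * 0.5)
        assert censored_paired_loglik(self.std, sample) == pytest.approx(
            expected, abs=1e-10
        )

    def test_uncensored_limit_is_bivariate_normal(self, rng):
        y1 = rng.standard_normal(30)
        y2 = rng.standard_normal(30)
        sample = make_paired(y1, y2)
        params = PairedTobitParams(0.1, -0.2, 1.2, 0.8, 0.4)
        ref = multivariate_normal(
            [0.1, -0.2], [[1.2, 0.4], [0.4, 0.8]]
        ).logpdf(np.column_stack([y1, y2])).sum()
        assert censored_paired_loglik(params, sample) == pytest.approx(ref)

    def test_matches_gauss_hermite_factor_integral(self, rng):
        """The marginal censored-bivariate likelihood equals 64-node
        Gauss-Hermite integration over the common factor, subject by
        subject, whenever the factor decomposition exists."""
        nodes, weights = np.polynomial.hermite.hermgauss(64)
        eta = np.sqrt(2.0) * nodes
        for trial in range(5):
            lam1, lam2 = rng.uniform(0.4, 1.2, size=2)
            sig_e = rng.uniform(0.4, 1.0)
            a, b = -1.0, 1.0
            mu1, mu2 = rng.normal(scale=0.3, size=2)
            params = PairedTobitParams(
                mu1, mu2, lam1**2 + sig_e**2, lam2**2 + sig_e**2, lam1 * lam2
            )
            true = rng.multivariate_normal(
                [mu1, mu2],
                [[params.var1, params.cov], [params.cov, params.var2]],
                size=8,
            )
            sample = make_paired(
                np.clip(true[:, 0], a, b), np.clip(true[:, 1], a, b),
                floor=a, ceiling=b,
            )
            for i in range(sample.n):
                per = 1.0
                for t, (y, stat, lam, mu) in enumerate(
                    [
                        (sample.pre.values[i], sample.pre.status[i], lam1, mu1),
                        (sample.post.values[i], sample.post.status[i], lam2, mu2),
                    ]
                ):
                    m = mu + lam * eta
                    if stat == 0:
                        per = per * norm.pdf(y, loc=m, scale=sig_e)
                    elif stat == 1:
                        per = per * norm.sf(b, loc=m, scale=sig_e)
                    else:
                        per = per * norm.cdf(a, loc=m, scale=sig_e)
                gh = np.log(np.sum(weights * per) / np.sqrt(np.pi))
                one = make_paired(
                    [sample.pre.values[i]], [sample.post.values[i]],
                    floor=a, ceiling=b,
                )
                assert censored_paired_loglik(params, one) == pytest.approx(
                    gh, abs=1e-6
                )


class TestFactorSolution:
    def test_symmetric_case(self):
        sol = factor_solution(PairedTobitParams(0, 0, 1.0, 1.0, 0.5))
        assert sol.exists
        assert sol.sigma_e2 == pytest.approx(0.5)
        assert abs(sol.lambda1) == pytest.approx(np.sqrt(0.5), abs=1e-6)
        assert sol.lambda1 * sol.lambda2 == pytest.approx(0.5)

    def test_asymmetric_case(self):
        sol = factor_solution(PairedTobitParams(0, 0, 1.0, 2.25, 0.5))
        assert sol.sigma_e2 == pytest.approx(0.8246, abs=5e-5)
        assert sol.lambda1**2 == pytest.approx(0.1754, abs=5e-5)
        assert sol.lambda2**2 == pytest.approx(1.4254, abs=5e-4)
        assert sol.lambda1 * sol.lambda2 == pytest.approx(0.5)

    def test_zero_covariance_boundary(self):
        sol = factor_solution(PairedTobitParams(0, 0, 1.0, 2.0, 0.0))
        assert sol.exists
        assert sol.sigma_e2 == pytest.approx(1.0)
        assert sol.lambda1 == pytest.approx(0.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        v1=st.floats(0.1, 5.0),
        v2=st.floats(0.1, 5.0),
        r=st.floats(-0.95, 0.95),
    )
    def test_reconstructs_implied_moments(self, v1, v2, r):
        c = r * np.sqrt(v1 * v2)
        sol = factor_solution(PairedTobitParams(0, 0, v1, v2, c))
        if not sol.exists:
            return
        assert sol.lambda1**2 + sol.sigma_e2 == pytest.approx(v1, rel=1e-7)
        assert sol.lambda2**2 + sol.sigma_e2 == pytest.approx(v2, rel=1e-7)
        assert sol.lambda1 * sol.lambda2 == pytest.approx(c, abs=1e-6)


class TestFit:
    def test_no_censoring_equals_sample_moments(self, uncensored_paired_sample):
        fit = TobitPairedTTest(uncensored_paired_sample).fit()
        y1 = uncensored_paired_sample.pre.values
        y2 = uncensored_paired_sample.post.values
        assert fit.converged
        assert fit.params.mu1 == pytest.approx(np.mean(y1), abs=1e-5)
        assert fit.params.mu2 == pytest.approx(np.mean(y2), abs=1e-5)
        assert fit.params.var1 == pytest.approx(np.var(y1), rel=1e-4)
        assert fit.params.var2 == pytest.approx(np.var(y2), rel=1e-4)
        assert fit.params.cov == pytest.approx(
            np.cov(y1, y2, ddof=0)[0, 1], rel=1e-4
        )

    def test_no_censoring_t_equals_conventional(self, uncensored_paired_sample):
        fit = TobitPairedTTest(uncensored_paired_sample).fit()
        tobit = fit.ttest(se="model")
        conv = PairedTTest(uncensored_paired_sample).fit("n")
        assert tobit.t_stat == pytest.approx(conv.t_stat, abs=1e-6)
        assert tobit.cohens_d == pytest.approx(conv.cohens_d, abs=1e-6)
        # without censoring the information SE coincides with the
        # model-implied one (up to numerical-Hessian error)
        info = fit.ttest(se="information")
        assert info.se == pytest.approx(tobit.se, rel=1e-3)

    def test_loglik_improves_on_start(self, censored_paired_sample):
        fit = TobitPairedTTest(censored_paired_sample).fit()
        assert fit.llf >= fit.start_llf

    def test_recovers_generating_parameters(self):
        cond = PairedCondition(d=0.5, sdr=1.5, rho=0.5, cp=0.2, n=2000, seed=7)
        fit = TobitPairedTTest(gen_paired(cond)).fit()
        assert fit.converged
        truth = np.array(
            [0.0, cond.mu2, 1.0, cond.sdr**2, cond.rho * cond.sdr]
        )
        assert np.all(np.abs(fit.params.as_array() - truth) < 3 * fit.bse)

    def test_fully_censored_variable_rejected(self):
        with pytest.raises(ValueError, match="interior"):
            TobitPairedTTest(make_paired([1.0, 1.0], [0.1, 0.2], ceiling=1.0))


class TestTTestFromParams:
    def test_zero_difference(self):
        res = paired_tobit_ttest(PairedTobitParams(1.0, 1.0, 1.0, 1.0, 0.2), 50)
        assert res.t_stat == 0.0 and res.p_value == 1.0 and res.cohens_d == 0.0

    def test_unit_statistic(self):
        # diff variance n and mean difference 1 give t exactly 1
        n = 16
        res = paired_tobit_ttest(PairedTobitParams(0.0, 1.0, n / 2, n / 2, 0.0), n)
        assert res.t_stat == pytest.approx(1.0)

    def test_normal_reference_narrows_interval(self):
        params = PairedTobitParams(0.0, 0.4, 1.0, 1.2, 0.3)
        t_ref = paired_tobit_ttest(params, 30, "t")
        z_ref = paired_tobit_ttest(params, 30, "normal")
        assert z_ref.ci95[1] - z_ref.ci95[0] < t_ref.ci95[1] - t_ref.ci95[0]
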