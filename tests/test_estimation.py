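import numpy as np
import pytest
from scipy import optimize
from sklearn.base import clone

import neitl.estimation as est_mod
from neitl import (
    BayesianEstimator,
    FitResult,
    LifetimeSample,
    MaximumLikelihoodEstimator,
    MaxSpacingEstimator,
    NEITLParams,
    NonConvergenceError,
    PriorSpec,
    asymptotic_ci,
    bayes_fit,
    bootstrap_ci,
    fit_mle,
    fit_mps,
    log_likelihood,
    log_posterior,
    mps_objective,
    neitl_cdf,
    neitl_logpdf,
    neitl_pdf,
    neitl_rvs,
    score,
    sf_hf_at_time,
)


class TestLogLikelihood:
    def test_single_observation_equals_logpdf(self):
        p = NEITLParams(1.3, 0.8)
        s = LifetimeSample([2.5])
        assert log_likelihood(p, s) == pytest.approx(neitl_logpdf(2.5, p), abs=1e-12)

    def test_termwise_sum_through_plain_density(self, pigs):
        """The log-stable path equals summing logs of the plain density."""
        p = NEITLParams(2.0, 1.0)
        direct = float(np.sum(np.log(neitl_pdf(pigs.values, p))))
        assert log_likelihood(p, pigs) == pytest.approx(direct, abs=1e-10)

    def test_tabulated_aic_at_reported_optimum(self, pigs):
        """At the published survival-times optimum the AIC reproduces 193.16."""
        ll = log_likelihood(NEITLParams(60.9983, 0.0299), pigs)
        assert 4 - 2 * ll == pytest.approx(193.1635, abs=0.01)

    def test_invalid_params_signalled(self):
        with pytest.raises(ValueError):
            NEITLParams(-1.0, 1.0)


class TestScore:
    @pytest.mark.parametrize("theta, delta", [(2.0, 1.0), (0.7, 3.0), (5.0, 0.2)])
    def test_matches_numeric_gradient(self, pigs, theta, delta):
        g = score(NEITLParams(theta, delta), pigs)
        num = optimize.approx_fprime(
            np.array([theta, delta]),
            lambda v: log_likelihood(NEITLParams(v[0], v[1]), pigs),
            1e-7 * np.array([theta, delta]),
        )
        assert g[0] == pytest.approx(num[0], rel=1e-4)
        assert g[1] == pytest.approx(num[1], rel=1e-4)

    def test_single_point_gradient(self):
        """n = 1 sample against a tight central difference."""
        p = NEITLParams(1.5, 2.5)
        s = LifetimeSample([0.9])
        g = score(p, s)
        h = 1e-6
        d_th = (
            log_likelihood(NEITLParams(1.5 + h, 2.5), s)
            - log_likelihood(NEITLParams(1.5 - h, 2.5), s)
        ) / (2 * h)
        d_de = (
            log_likelihood(NEITLParams(1.5, 2.5 + h), s)
            - log_likelihood(NEITLParams(1.5, 2.5 - h), s)
        ) / (2 * h)
        assert g[0] == pytest.approx(d_th, rel=1e-6)
        assert g[1] == pytest.approx(d_de, rel=1e-6)

    def test_vanishes_at_optimum(self, group_fits, group1):
        f1 = group_fits[0]
        g = score(f1.params, group1)
        assert abs(g[0]) < 1e-3 and abs(g[1]) < 1e-3


class TestFitMLE:
    def test_group1_reproduces_published_estimates(self, group_fits):
        f1 = group_fits[0]
        assert f1.params.theta == pytest.approx(0.4244, rel=2e-3)
        assert f1.params.delta == pytest.approx(5.6463, rel=2e-3)
        assert f1.converged

    def test_survival_times_fit_beats_reported_point(self, pigs_ml, pigs):
        """The multi-start optimum dominates the published ridge point."""
        assert pigs_ml.objective >= log_likelihood(
            NEITLParams(60.9983, 0.0299), pigs
        )
        assert 4 - 2 * pigs_ml.objective == pytest.approx(193.1635, abs=0.01)

    def test_parameter_recovery_large_sample(self):
        truth = NEITLParams(3.0, 3.0)
        s = neitl_rvs(5000, truth, seed=31)
        fit = fit_mle(s)
        for est, se, true in zip(
            fit.params.as_tuple(), fit.std_errors, truth.as_tuple()
        ):
            assert abs(est - true) < 3 * se

    def test_permutation_invariance(self, rng):
        s = neitl_rvs(80, NEITLParams(2.0, 2.0), seed=3).values
        a = fit_mle(LifetimeSample(s))
        b = fit_mle(LifetimeSample(rng.permutation(s)))
        assert a.params.theta == pytest.approx(b.params.theta, rel=1e-6)
        assert a.params.delta == pytest.approx(b.params.delta, rel=1e-6)

    def test_requires_two_observations(self):
        with pytest.raises(ValueError):
            fit_mle(LifetimeSample([1.0]))

    def test_no_starts_rejected(self):
        s = neitl_rvs(20, NEITLParams(1, 1), seed=0)
        with pytest.raises(ValueError):
            fit_mle(s, include_default_starts=False)


class TestMPS:
    def test_single_observation_closed_form(self):
        p = NEITLParams(1.2, 0.9)
        s = LifetimeSample([1.7])
        F = neitl_cdf(1.7, p)
        expected = 0.5 * (np.log(F) + np.log1p(-F))
        assert mps_objective(p, s) == pytest.approx(expected, abs=1e-12)

    def test_am_gm_bound(self, rng):
        """Mean log spacing can never beat uniform spacings."""
        s = neitl_rvs(19, NEITLParams(1.5, 1.5), seed=8)
        bound = np.log(1.0 / (len(s) + 1))
        for _ in range(10):
            p = NEITLParams(rng.uniform(0.2, 4), rng.uniform(0.2, 4))
            assert mps_objective(p, s) <= bound + 1e-12

    def test_tie_handling_keeps_objective_finite(self):
        s = LifetimeSample([0.5, 1.07, 1.07, 2.3])
        val = mps_objective(NEITLParams(1.0, 1.0), s)
        assert np.isfinite(val)

    def test_group1_matches_published_block(self, group_fits):
        m1 = group_fits[2]
        # the spacing surface is flat to ~1e-5 around this mode; the
        # published (0.4143, 5.4284) and this optimum agree to ~2%
        assert m1.params.theta == pytest.approx(0.4143, rel=0.05)
        assert m1.params.delta == pytest.approx(5.4284, rel=0.06)

    def test_objective_dominates_published_point(self, group_fits, group1):
        m1 = group_fits[2]
        assert m1.objective >= mps_objective(NEITLParams(0.4143, 5.4284), group1)

    def test_large_sample_agrees_with_ml(self):
        s = neitl_rvs(10_000, NEITLParams(2.0, 2.0), seed=17)
        ml = fit_mle(s, n_grid=3)
        mps = fit_mps(s, ml_result=ml)
        assert mps.params.theta == pytest.approx(ml.params.theta, rel=0.1)
        assert mps.params.delta == pytest.approx(ml.params.delta, rel=0.1)


class TestBayes:
    def test_prior_only_sampling_recovers_gamma_prior(self):
        prior = PriorSpec(a1=2.0, b1=1.0, a2=3.0, b2=2.0)
        draws = bayes_fit(None, prior=prior, n_iter=20_000, burn_in=4_000, seed=5)
        assert draws.theta.mean() == pytest.approx(2.0, rel=0.1)
        assert draws.delta.mean() == pytest.approx(1.5, rel=0.1)
        assert draws.theta.var(ddof=1) == pytest.approx(2.0, rel=0.3)

    def test_deterministic_given_seed(self):
        s = neitl_rvs(40, NEITLParams(1.0, 1.0), seed=2)
        a = bayes_fit(s, n_iter=500, burn_in=100, seed=9)
        b = bayes_fit(s, n_iter=500, burn_in=100, seed=9)
        assert np.array_equal(a.theta_chain, b.theta_chain)

    def test_gelman_rubin_across_chains(self):
        """4 chains from different seeds mix to the same posterior."""
        s = neitl_rvs(150, NEITLParams(3.0, 3.0), seed=14)
        chains = [
            bayes_fit(s, n_iter=10_000, burn_in=2_000, seed=k).theta
            for k in range(4)
        ]
        m = len(chains)
        n = len(chains[0])
        means = np.array([c.mean() for c in chains])
        variances = np.array([c.var(ddof=1) for c in chains])
        W = variances.mean()
        B = n * means.var(ddof=1)
        var_hat = (n - 1) / n * W + B / n
        assert np.sqrt(var_hat / W) < 1.05

    def test_flat_prior_posterior_close_to_mle_large_n(self):
        s = neitl_rvs(2000, NEITLParams(3.0, 3.0), seed=21)
        ml = fit_mle(s, n_grid=3)
        draws = bayes_fit(
            s,
            prior=PriorSpec(1.0, 1e-4, 1.0, 1e-4),
            n_iter=4000,
            burn_in=1000,
            seed=3,
            start=ml.params,
        )
        pm = draws.point_estimate()
        assert abs(pm.theta - ml.params.theta) < ml.std_errors[0]
        assert abs(pm.delta - ml.params.delta) < ml.std_errors[1]

    def test_flat_prior_shifts_logposterior_by_constant(self):
        s = neitl_rvs(30, NEITLParams(1.0, 1.0), seed=4)
        prior = PriorSpec(1.0, 1e-9, 1.0, 1e-9)
        diffs = [
            log_posterior(p, s, prior) - log_likelihood(p, s)
            for p in (NEITLParams(0.5, 2.0), NEITLParams(3.0, 0.3))
        ]
        assert diffs[0] == pytest.approx(diffs[1], abs=1e-6)

    def test_conditional_factorisation(self):
        """Joint log posterior differences isolate each parameter's terms."""
        s = neitl_rvs(25, NEITLParams(1.0, 1.0), seed=6)
        prior = PriorSpec()
        th0, th1, de = 0.8, 1.7, 1.2
        joint_diff = log_posterior(NEITLParams(th1, de), s, prior) - log_posterior(
            NEITLParams(th0, de), s, prior
        )
        # the delta-only terms cancel, so the difference is the theta
        # conditional's difference
        cond = (
            log_likelihood(NEITLParams(th1, de), s)
            - log_likelihood(NEITLParams(th0, de), s)
            + (prior.a1 - 1) * np.log(th1 / th0)
            - prior.b1 * (th1 - th0)
        )
        assert joint_diff == pytest.approx(cond, abs=1e-10)

    def test_burn_in_validation(self):
        with pytest.raises(ValueError):
            bayes_fit(None, n_iter=100, burn_in=100, seed=0)


class TestIntervals:
    def test_wald_length_for_unit_se(self):
        fit = FitResult(
            method="ML",
            params=NEITLParams(1.0, 1.0),
            std_errors=(1.0, 1.0),
            objective=0.0,
            converged=True,
            n=10,
            cov=np.eye(2),
        )
        ci_t, ci_d = asymptotic_ci(fit, level=0.95)
        assert ci_t.length == pytest.approx(3.9199, abs=1e-3)

    def test_singular_information_signalled(self):
        fit = FitResult(
            method="ML",
            params=NEITLParams(1.0, 1.0),
            std_errors=(np.nan, np.nan),
            objective=0.0,
            converged=True,
            n=10,
            cov=None,
        )
        with pytest.raises(NonConvergenceError):
            asymptotic_ci(fit)

    def test_wald_coverage_simulation(self):
        """~95% of Wald intervals cover the truth at n = 500."""
        truth = NEITLParams(3.0, 3.0)
        hits = np.zeros(2)
        n_rep = 60
        for k in range(n_rep):
            s = neitl_rvs(500, truth, seed=1000 + k)
            fit = fit_mle(s, starts=[truth], include_default_starts=False)
            try:
                cis = asymptotic_ci(fit)
            except NonConvergenceError:
                continue
            for i, (ci, true) in enumerate(zip(cis, truth.as_tuple())):
                hits[i] += ci.lower <= true <= ci.upper
        coverage = hits / n_rep
        assert np.all(coverage > 0.85) and np.all(coverage <= 1.0)

    def test_bootstrap_interval_widens_with_level(self):
        s = neitl_rvs(60, NEITLParams(2.0, 2.0), seed=12)
        lo = bootstrap_ci(s, B=120, level=0.8, seed=5)
        hi = bootstrap_ci(s, B=120, level=0.99, seed=5)
        assert hi[0].length > lo[0].length
        assert hi[1].length > lo[1].length

    def test_bootstrap_requires_enough_resamples(self):
        s = neitl_rvs(30, NEITLParams(1.0, 1.0), seed=1)
        with pytest.raises(ValueError):
            bootstrap_ci(s, B=50)

    def test_bootstrap_failure_rate_contract(self, monkeypatch):
        s = neitl_rvs(30, NEITLParams(1.0, 1.0), seed=1)

        def failing_fit(*args, **kwargs):
            raise NonConvergenceError("forced failure")

        monkeypatch.setattr(est_mod, "fit_mle", failing_fit)
        with pytest.raises(NonConvergenceError):
            bootstrap_ci(s, B=100, seed=0)


class TestSfHfAtTime:
    def test_plug_in_identity(self, group_fits):
        f1 = group_fits[0]
        rec = sf_hf_at_time(f1, 1.5)
        from neitl import neitl_hf, neitl_sf

        assert rec["R"] == pytest.approx(neitl_sf(1.5, f1.params), abs=1e-12)
        assert rec["H"] == pytest.approx(neitl_hf(1.5, f1.params), rel=1e-10)

    def test_delta_method_interval_covers_truth_large_n(self):
        truth = NEITLParams(3.0, 0.5)
        s = neitl_rvs(1000, truth, seed=77)
        fit = fit_mle(s, starts=[truth], include_default_starts=False)
        from neitl import neitl_sf

        rec = sf_hf_at_time(fit, 0.25)
        true_R = neitl_sf(0.25, truth)
        assert rec["ci_R"] is not None
        assert rec["ci_R"].lower - 0.02 <= true_R <= rec["ci_R"].upper + 0.02

    def test_q_validation(self, group_fits):
        with pytest.raises(ValueError):
            sf_hf_at_time(group_fits[0], 0.0)


class TestSklearnEstimators:
    def test_mle_estimator_protocol(self):
        X = neitl_rvs(200, NEITLParams(2.0, 2.0), seed=50).values
        est = MaximumLikelihoodEstimator(n_grid=3)
        assert clone(est).get_params() == est.get_params()
        est.fit(X)
        assert est.theta_ > 0 and est.delta_ > 0
        assert np.isfinite(est.loglik_)
        assert est.score_samples(X[:5]).shape == (5,)
        draws = est.sample(10, random_state=0)
        assert draws.shape == (10,) and np.all(draws > 0)
        assert est.score(X) == pytest.approx(est.loglik_ / len(X), rel=1e-12)

    def test_mps_estimator(self):
        X = neitl_rvs(100, NEITLParams(2.0, 2.0), seed=51).values.reshape(-1, 1)
        est = MaxSpacingEstimator().fit(X)
        assert est.objective_ <= np.log(1.0 / (len(X) + 1)) + 1e-12

    def test_bayes_estimator(self):
        X = neitl_rvs(60, NEITLParams(1.0, 1.0), seed=52).values
        est = BayesianEstimator(n_iter=800, burn_in=200, random_state=7).fit(X)
        assert est.theta_ > 0 and est.posterior_.theta.size == 600
        ci_t, ci_d = est.posterior_.credible_interval()
        assert ci_t.lower < est.theta_ < ci_t.upper
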