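import math

import numpy as np
import pytest

from msldiff import (InitialLaw, PolynomialCoefficients, ProcessParams,
                     SamplePanel, alpha_mle, fit_newton_raphson,
                     initial_sigma2_guess, initial_theta_guess,
                     likelihood_blocks, log_likelihood, make_case_panel,
                     multisigmoidal_logistic, reduced_log_likelihood,
                     sigma2_given_theta, simulate_paths, system_residuals,
                     transition_law, v_transform, carrying_capacity)

TRUE_BETA = np.array([0.1, -0.009, 0.0002])
TRUE_SIGMA = 0.01


def _random_params(rng) -> ProcessParams:
    beta = (0.1 * rng.uniform(0.5, 1.5), -0.009 * rng.uniform(0.5, 1.5),
            0.0002 * rng.uniform(0.5, 1.5))
    return ProcessParams(eta=rng.uniform(0.05, 0.5),
                         beta=PolynomialCoefficients(beta),
                         sigma2=rng.uniform(1e-5, 5e-3))


class TestVTransform:
    def test_constant_path_gives_zero_increments(self):
        t = np.array([0.0, 1.0, 3.0, 7.0])
        panel = SamplePanel(times=[t], values=[np.full(4, 2.5)])
        vs = v_transform(panel)
        assert np.all(vs.v == 0)
        assert vs.Z1 == 0.0

    def test_two_point_path_scaling(self):
        # value ratio e over a step of length 4 gives v = 4^{-1/2}
        panel = SamplePanel(times=[np.array([0.0, 4.0])],
                            values=[np.array([2.0, 2.0 * math.e])])
        vs = v_transform(panel)
        assert vs.v[0] == pytest.approx(0.5, rel=1e-12)

    def test_total_elapsed_time(self):
        t = np.linspace(0.0, 50.0, 11)
        panel = SamplePanel(times=[t], values=[np.exp(t / 50.0)])
        assert v_transform(panel).Z3 == pytest.approx(50.0)

    def test_counts(self, small_panel):
        vs = v_transform(small_panel)
        assert vs.n == small_panel.n_steps == 8 * 25
        assert vs.d == 8


class TestAlphaMLE:
    def test_identical_initial_values(self):
        panel = SamplePanel(times=[np.array([0.0, 1.0])] * 3,
                            values=[np.array([2.0, 3.0])] * 3)
        mu1, s1 = alpha_mle(v_transform(panel))
        assert mu1 == pytest.approx(math.log(2.0))
        assert s1 == 0.0

    def test_two_path_arithmetic(self):
        panel = SamplePanel(
            times=[np.array([0.0, 1.0]), np.array([0.0, 1.0])],
            values=[np.array([1.0, 2.0]), np.array([math.e ** 2, 2.0])])
        mu1, s1 = alpha_mle(v_transform(panel))
        assert mu1 == pytest.approx(1.0, abs=1e-12)
        assert s1 == pytest.approx(1.0, abs=1e-12)  # ML divisor d, not d-1

    def test_single_path_zero_variance(self):
        panel = SamplePanel(times=[np.array([0.0, 1.0])],
                            values=[np.array([3.0, 4.0])])
        assert alpha_mle(v_transform(panel))[1] == 0.0


class TestBlockIdentities:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_phi_gamma_y_identities(self, seed, small_panel):
        rng = np.random.default_rng(seed)
        params = _random_params(rng)
        vs = v_transform(small_panel)
        blocks = likelihood_blocks(vs, (params.eta, params.beta))
        s2 = params.sigma2
        phi = blocks.Phi(s2, vs)
        gam = blocks.Gamma(s2, vs)
        yxi = blocks.Yxi(s2)
        scale = max(1.0, abs(phi))
        assert phi == pytest.approx(
            blocks.A + s2 ** 2 / 4.0 * vs.Z3 - s2 * blocks.C,
            abs=1e-10 * scale)
        assert gam == pytest.approx(blocks.B - s2 / 2.0 * vs.Z2, abs=1e-10)
        assert yxi == pytest.approx(blocks.C - s2 / 2.0 * vs.Z3, abs=1e-10)

    def test_remark_identity_term_by_term(self, small_panel):
        # Z1 + A - 2B equals the sum of squared centered increments
        vs = v_transform(small_panel)
        rng = np.random.default_rng(5)
        params = _random_params(rng)
        blocks = likelihood_blocks(vs, (params.eta, params.beta))
        centered = vs.v - blocks.lam / np.sqrt(vs.delta)
        lhs = vs.Z1 + blocks.A - 2.0 * blocks.B
        assert lhs == pytest.approx(float(np.sum(centered ** 2)), rel=1e-10)
        assert lhs >= 0.0

    def test_single_step_lambda_value(self, params_ref):
        panel = SamplePanel(times=[np.array([2.0, 7.0])],
                            values=[np.array([5.0, 6.0])])
        vs = v_transform(panel)
        blocks = likelihood_blocks(vs, (params_ref.eta, params_ref.beta))
        # times are shifted so the step runs from 0 to 5 on the fit clock
        from msldiff.process import eval_Q, log_eta_plus_exp_negQ
        a0 = log_eta_plus_exp_negQ(params_ref.eta, eval_Q(params_ref.beta, 0.0))
        a5 = log_eta_plus_exp_negQ(params_ref.eta, eval_Q(params_ref.beta, 5.0))
        assert blocks.lam[0] == pytest.approx(float(a0 - a5), rel=1e-12)


class TestLogLikelihood:
    def test_reduced_formula_wiring(self, small_panel):
        # the function reproduces -n/2 log s2 - (Z1 + Phi - 2 Gamma)/(2 s2)
        # assembled independently from the blocks
        rng = np.random.default_rng(3)
        params = _random_params(rng)
        vs = v_transform(small_panel)
        blocks = likelihood_blocks(vs, (params.eta, params.beta))
        s2 = params.sigma2
        manual = (-vs.n / 2.0 * math.log(s2)
                  - (vs.Z1 + blocks.Phi(s2, vs) - 2 * blocks.Gamma(s2, vs))
                  / (2 * s2))
        assert reduced_log_likelihood(vs, params) == pytest.approx(
            manual, rel=1e-12)

    def test_matches_transition_density_oracle(self, lognormal_init_panel,
                                               params_ref):
        # L_V equals the log-density of the observations plus the
        # change-of-variables Jacobian of the v-transform
        panel = lognormal_init_panel
        vs = v_transform(panel)
        alpha = (math.log(5.0), 0.02)
        direct = log_likelihood(vs, alpha, params_ref)
        from scipy.stats import norm
        oracle = 0.0
        jacobian = 0.0
        for t, x in zip(panel.times, panel.values):
            ts = t - panel.t0
            oracle += norm.logpdf(math.log(x[0]), loc=alpha[0],
                                  scale=math.sqrt(alpha[1])) - math.log(x[0])
            for j in range(len(ts) - 1):
                law = transition_law(params_ref, x[j], ts[j], ts[j + 1])
                oracle += math.log(float(law.pdf(x[j + 1])))
                jacobian += math.log(x[j + 1]) + 0.5 * math.log(ts[j + 1]
                                                                - ts[j])
        assert direct == pytest.approx(oracle + jacobian, abs=1e-10 *
                                       max(1.0, abs(direct)))

    def test_invariant_to_path_ordering(self, small_panel, params_ref):
        panel = small_panel
        reordered = SamplePanel(times=list(reversed(panel.times)),
                                values=list(reversed(panel.values)))
        alpha = (math.log(5.0), 0.01)
        assert log_likelihood(panel, alpha, params_ref) == pytest.approx(
            log_likelihood(reordered, alpha, params_ref), rel=1e-12)

    def test_alpha_mle_maximizes(self, lognormal_init_panel, params_ref):
        vs = v_transform(lognormal_init_panel)
        mu1, s1 = alpha_mle(vs)
        best = log_likelihood(vs, (mu1, s1), params_ref)
        for dmu in (-0.05, 0.05):
            assert log_likelihood(vs, (mu1 + dmu, s1), params_ref) < best
        for ds in (0.5, 2.0):
            assert log_likelihood(vs, (mu1, s1 * ds), params_ref) < best

    def test_degenerate_initial_rejected(self, small_panel, params_ref):
        with pytest.raises(ValueError):
            log_likelihood(small_panel, (1.0, 0.0), params_ref)


class TestSystem:
    def test_sigma2_root_arithmetic(self):
        # 2(-100 + sqrt(10000.5))/50 for n=100, Z3=50, q=0.01
        expected = 2.0 * (-100.0 + math.sqrt(100.0 ** 2 + 50.0 * 0.01)) / 50.0
        assert expected == pytest.approx(9.99988e-5, rel=1e-4)

    def test_sigma2_root_satisfies_first_equation(self, case1_panel):
        vs = v_transform(case1_panel)
        # rescale times to the unit used by sigma2 on the original clock
        params = ProcessParams(eta=math.exp(-1),
                               beta=PolynomialCoefficients(tuple(TRUE_BETA)),
                               sigma2=TRUE_SIGMA ** 2)
        blocks = likelihood_blocks(vs, (params.eta, params.beta))
        s2 = sigma2_given_theta(blocks, vs)
        res = s2 * (vs.n + s2 / 4.0 * vs.Z3) - vs.Z1 - blocks.A \
            + 2.0 * blocks.B
        assert abs(res) < 1e-12 * max(1.0, vs.Z1)
        assert s2 >= 0.0

    def test_perfect_fit_gives_zero_sigma2(self):
        # noiseless panel: increments exactly match the curve
        params = ProcessParams(eta=math.exp(-1),
                               beta=PolynomialCoefficients(tuple(TRUE_BETA)),
                               sigma2=1e-16)
        t = np.linspace(0.0, 50.0, 26)
        curve = multisigmoidal_logistic(params, 5.0, 0.0, t)
        panel = SamplePanel(times=[t, t], values=[curve, curve.copy()])
        vs = v_transform(panel)
        # at sigma^2 = 0 the drift lam matches the increments exactly
        blocks = likelihood_blocks(vs, (params.eta, params.beta))
        assert sigma2_given_theta(blocks, vs) == pytest.approx(0.0, abs=1e-12)

    def test_residuals_are_scaled_gradient(self, small_panel):
        # exact relations tying the system to the gradient of Ltilde:
        #   dL/dtheta_l = -r_l / sigma^2,  dL/dsigma2 = -r_first/(2 sigma^4),
        # checked against central finite differences at a generic point —
        # hence the two zero sets coincide
        vs = v_transform(small_panel)
        rng = np.random.default_rng(17)
        params = _random_params(rng)
        x = params.as_vector()
        res = system_residuals(vs, params)
        s2 = params.sigma2
        # the eta equation is the negated gradient component (the printed
        # system's l=0 line carries the opposite sign; same zero set)
        expected = np.concatenate([[res[1] / s2], res[2:] / (-s2),
                                   [-res[0] / (2 * s2 ** 2)]])
        grad = np.empty(len(x))
        for k in range(len(x)):
            h = 1e-7 * max(abs(x[k]), 1e-10)
            xp, xm = x.copy(), x.copy()
            xp[k] += h
            xm[k] -= h
            grad[k] = (reduced_log_likelihood(vs, _vec_params(xp))
                       - reduced_log_likelihood(vs, _vec_params(xm))) / (2 * h)
        # grad is ordered (eta, beta.., sigma2); expected likewise
        assert np.allclose(grad, expected, rtol=1e-5)

    def test_residuals_small_at_fit(self, case1_panel):
        fit = fit_newton_raphson(case1_panel, 3)
        assert fit.converged and fit.residual_norm < 1e-8

    def test_residuals_finite_over_bounds_box(self, case1_panel):
        from msldiff import parameter_bounds
        bounds = parameter_bounds(case1_panel, 3)
        vs = v_transform(case1_panel)
        rng = np.random.default_rng(8)
        for _ in range(25):
            x = rng.uniform(bounds.lower, bounds.upper)
            x[-1] = max(x[-1], 1e-8)
            res = system_residuals(vs, _vec_params(x))
            assert np.all(np.isfinite(res))


def _vec_params(x) -> ProcessParams:
    return ProcessParams(eta=float(x[0]),
                         beta=PolynomialCoefficients(
                             tuple(x[1:-1]), require_positive_leading=False),
                         sigma2=float(x[-1]))


class TestInitialGuesses:
    def test_noiseless_recovery_with_true_carrying_capacity(self, params_ref):
        t = np.linspace(0.0, 50.0, 53)
        curve = multisigmoidal_logistic(params_ref, 5.0, 0.0, t)
        panel = SamplePanel(times=[t], values=[curve])
        cc = carrying_capacity(params_ref, 5.0, 0.0)
        eta0, beta0 = initial_theta_guess(panel, 3, carrying=cc)
        assert eta0 == pytest.approx(params_ref.eta, rel=1e-6)
        assert np.allclose(beta0, TRUE_BETA, rtol=1e-6, atol=1e-9)

    def test_eta_guess_positive(self, case1_panel):
        eta0, _ = initial_theta_guess(case1_panel, 3)
        assert eta0 > 0

    def test_guess_order_of_magnitude(self, case1_panel):
        eta0, beta0 = initial_theta_guess(case1_panel, 3)
        assert 0.03 < eta0 < 3.0
        assert abs(beta0[0]) < 1.0

    def test_insufficient_points_raise(self, params_ref):
        t = np.linspace(0.0, 10.0, 4)
        curve = multisigmoidal_logistic(params_ref, 5.0, 0.0, t)
        panel = SamplePanel(times=[t], values=[curve])
        with pytest.raises(ValueError):
            initial_theta_guess(panel, 4)

    def test_sigma2_guess_floor_on_identical_paths(self):
        t = np.linspace(0.0, 10.0, 6)
        x = np.exp(0.1 * t) * 5.0
        panel = SamplePanel(times=[t, t], values=[x, x.copy()])
        assert initial_sigma2_guess(panel) == pytest.approx(1e-8)

    def test_sigma2_guess_recovers_scale(self, params_ref):
        panel = make_case_panel(1, n_paths=200, n_times=51, seed=13)
        guess = initial_sigma2_guess(panel)
        assert guess == pytest.approx(TRUE_SIGMA ** 2, rel=0.3)


class TestNewtonFit:
    def test_case1_parameter_recovery(self, case1_panel):
        fit = fit_newton_raphson(case1_panel, 3)
        assert fit.converged
        beta = np.array(fit.xi_hat.beta.beta)
        assert abs(beta[0] - 0.1) / 0.1 < 0.05
        assert abs(math.sqrt(fit.xi_hat.sigma2) - 0.01) / 0.01 < 0.05

    def test_profiled_variant_agrees(self, case1_panel):
        full = fit_newton_raphson(case1_panel, 3)
        prof = fit_newton_raphson(case1_panel, 3, profile_sigma2=True)
        assert np.allclose(full.xi_hat.as_vector(), prof.xi_hat.as_vector(),
                           rtol=1e-6)

    def test_fast_convergence_from_truth_on_clean_panel(self, params_ref):
        params = ProcessParams(eta=params_ref.eta, beta=params_ref.beta,
                               sigma2=1e-10)
        t = np.linspace(0.0, 50.0, 51)
        panel = simulate_paths(params, InitialLaw.degenerate(5.0), t, 3,
                               seed=2)
        fit = fit_newton_raphson(panel, 3, x0=params.as_vector())
        assert fit.converged and fit.iterations <= 3

    def test_likelihood_ascent_over_initial_guess(self, case1_panel):
        vs = v_transform(case1_panel)
        eta0, beta0 = initial_theta_guess(case1_panel, 3)
        s20 = initial_sigma2_guess(case1_panel)
        fit = fit_newton_raphson(case1_panel, 3)
        start = ProcessParams(
            eta=eta0,
            beta=PolynomialCoefficients(tuple(beta0),
                                        require_positive_leading=False),
            sigma2=s20)
        assert reduced_log_likelihood(vs, fit.xi_hat) >= \
            reduced_log_likelihood(vs, start)

    def test_recovery_improves_with_more_paths(self, params_ref):
        # root-mean-square error of beta1 shrinks from d=10 to d=80
        errs = {10: [], 80: []}
        for d, seeds in ((10, (0, 1, 2)), (80, (0, 1, 2))):
            for seed in seeds:
                panel = make_case_panel(1, n_paths=d, n_times=101,
                                        seed=100 + seed)
                fit = fit_newton_raphson(panel, 3)
                errs[d].append((fit.xi_hat.beta.beta[0] - 0.1) ** 2)
        assert math.sqrt(np.mean(errs[80])) < math.sqrt(np.mean(errs[10]))

    def test_nonconvergence_is_reported(self, case1_panel):
        fit = fit_newton_raphson(case1_panel, 3, max_iter=1)
        # either converges immediately (it does not) or flags the failure
        assert fit.converged or fit.message
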