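import numpy as np
import pytest
from scipy.stats import beta as beta_dist
from scipy.stats import gumbel_r, multivariate_normal, truncnorm

from mblr.model_core import (
    RIDGE_FACTOR,
    ConditionalPosterior,
    DesignMatrix,
    FullPosterior,
    GlobalEffects,
    MagnitudeMatrix,
    ModelSpec,
    SignMatrix,
    gamma_from_delta,
    gumbel_softmax_delta,
    linear_predictor,
    log_joint_density,
    log_joint_density_conditional,
)

from conftest import random_problem


class TestGumbelSoftmaxDelta:
    def test_symmetric_arguments_give_half(self):
        for tau in (0.01, 0.5, 3.0):
            assert gumbel_softmax_delta(0.5, 1.3, 1.3, tau) == pytest.approx(0.5)

    def test_small_tau_approaches_argmax(self):
        # log(pi1) + g1 > log(1-pi1) + g_neg1 -> delta -> 1
        assert gumbel_softmax_delta(0.6, 0.5, 0.1, 1e-3) == pytest.approx(1.0, abs=1e-12)
        assert gumbel_softmax_delta(0.6, -3.0, 0.1, 1e-3) == pytest.approx(0.0, abs=1e-12)

    def test_derived_value(self):
        # independent evaluation of the two-class softmax with the stated inputs
        assert gumbel_softmax_delta(0.7, 0.1, -0.2, 1.0) == pytest.approx(0.7589, abs=5e-4)

    def test_overflow_scale_arguments(self):
        assert gumbel_softmax_delta(0.5, 4000.0, -4000.0, 1.0) == pytest.approx(1.0)

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            gumbel_softmax_delta(0.5, 0.0, 0.0, 0.0)

    def test_invalid_pi1(self):
        with pytest.raises(ValueError):
            gumbel_softmax_delta(1.0, 0.0, 0.0, 1.0)

    def test_exact_categorical_property(self):
        """At tau -> 0 the relaxation reproduces Bernoulli(pi1) exactly."""
        rng = np.random.default_rng(123)
        pi1 = 0.3
        n = 10_000
        delta = gumbel_softmax_delta(pi1, rng.gumbel(size=n), rng.gumbel(size=n), 0.01)
        frac = np.mean(delta > 0.5)
        se = np.sqrt(pi1 * (1 - pi1) / n)
        assert abs(frac - pi1) < 3 * se


class TestGammaFromDelta:
    @pytest.mark.parametrize("delta,expected", [(1.0, 1.0), (0.0, -1.0), (0.5, 0.0)])
    def test_values(self, delta, expected):
        assert gamma_from_delta(delta) == pytest.approx(expected)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            gamma_from_delta(1.5)


class TestLinearPredictor:
    def test_zero_beta_annihilates(self):
        gamma = np.array([[1.0, -1.0], [-1.0, 1.0]])
        beta = np.full((2, 2), 1e-300)
        np.testing.assert_allclose(linear_predictor(gamma, beta, np.array([3.0, -2.0])), 0.0, atol=1e-290)

    def test_small_example(self):
        mu = linear_predictor(np.array([[1.0], [-1.0]]), np.array([[2.0], [3.0]]), np.array([0.5]))
        np.testing.assert_allclose(mu, [1.0, -1.5])

    def test_sign_flip_negates(self, rng):
        gamma = np.where(rng.uniform(size=(4, 3)) < 0.5, 1.0, -1.0)
        beta = rng.uniform(0.1, 2.0, size=(4, 3))
        x = rng.normal(size=3)
        np.testing.assert_allclose(
            linear_predictor(-gamma, beta, x), -linear_predictor(gamma, beta, x)
        )

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            linear_predictor(np.ones((2, 2)), np.ones((2, 2)), np.ones(3))


def oracle_log_joint(params, y, design, cov, spec):
    """Term-wise oracle: every density coded separately with scipy.stats."""
    a = np.asarray(params["a"])
    beta = np.asarray(params["beta"])
    pi1 = params["pi1"]
    sigma = np.sqrt(spec.sigma2)
    delta = gumbel_softmax_delta(pi1, params["g1"], params["g_neg1"], spec.tau)
    gamma = 2.0 * delta - 1.0
    c_matrix = cov.values + RIDGE_FACTOR * np.mean(np.diag(cov.values)) * np.eye(cov.size)
    total = 0.0
    for i in range(y.values.shape[0]):
        mu_i = (gamma * beta) @ design.values[i]
        total += multivariate_normal.logpdf(y.values[i], mu_i, c_matrix)
    for s in range(beta.shape[0]):
        for j in range(beta.shape[1]):
            total += truncnorm.logpdf(beta[s, j], -a[j] / sigma, np.inf, loc=a[j], scale=sigma)
    for j in range(a.size):
        total += truncnorm.logpdf(a[j], 0.0, np.inf, loc=0.0, scale=1.0)
    total += beta_dist.logpdf(pi1, spec.pi1_alpha, spec.pi1_beta)
    total += gumbel_r.logpdf(params["g1"]).sum() + gumbel_r.logpdf(params["g_neg1"]).sum()
    return total


def random_params(rng, s1, p):
    return {
        "a": rng.uniform(0.05, 2.0, size=p),
        "beta": rng.uniform(0.05, 2.5, size=(s1, p)),
        "g1": rng.gumbel(size=(s1, p)),
        "g_neg1": rng.gumbel(size=(s1, p)),
        "pi1": rng.uniform(0.1, 0.9),
    }


class TestLogJointDensity:
    def test_matches_termwise_oracle(self, rng):
        y, design, cov, spec = random_problem(rng)
        for _ in range(10):
            params = random_params(rng, 3, 2)
            ours = log_joint_density(params, y, design, cov, spec)
            theirs = oracle_log_joint(params, y, design, cov, spec)
            assert ours == pytest.approx(theirs, abs=1e-8)

    def test_univariate_limit(self, rng):
        """With c*Sigma = I and S-1 = 1 the MVN term is the univariate Gaussian density."""
        y, design, cov, spec = random_problem(rng, n=8, s1=1)
        params = random_params(rng, 1, 2)
        ours = log_joint_density(params, y, design, cov, spec)
        theirs = oracle_log_joint(params, y, design, cov, spec)
        assert ours == pytest.approx(theirs, abs=1e-8)

    def test_covariance_scaling_closed_form(self, rng):
        """Doubling c changes the MVN part by -n(S-1)/2 log 2 - quad/2 rescaling."""
        from mblr.phylo import model_covariance

        y, design, cov, spec = random_problem(rng)
        cov2 = model_covariance(None, [f"taxon{j}" for j in range(3)] + ["ref"], "ref", scale_c=2.0)
        params = random_params(rng, 3, 2)
        lp1 = log_joint_density(params, y, design, cov, spec)
        lp2 = log_joint_density(params, y, design, cov2, spec)
        # recompute the two MVN pieces directly
        delta = gumbel_softmax_delta(params["pi1"], params["g1"], params["g_neg1"], spec.tau)
        effects = (2 * delta - 1) * params["beta"]
        resid = y.values - design.values @ effects.T
        quad = np.sum(resid**2)  # identity covariance (ridge is negligible here)
        n, s1 = y.values.shape
        expected_gap = -0.5 * n * s1 * np.log(2.0) - 0.5 * (quad / 2.0 - quad)
        assert lp2 - lp1 == pytest.approx(expected_gap, rel=1e-6)

    def test_out_of_support(self, rng):
        y, design, cov, spec = random_problem(rng)
        params = random_params(rng, 3, 2)
        bad = dict(params, beta=params["beta"] * -1)
        assert log_joint_density(bad, y, design, cov, spec) == -np.inf
        bad = dict(params, a=params["a"] - 10)
        assert log_joint_density(bad, y, design, cov, spec) == -np.inf

    def test_conditional_matches_oracle(self, rng):
        y, design, cov, spec = random_problem(rng)
        signs = np.where(rng.uniform(size=(3, 2)) < 0.5, 1.0, -1.0)
        params = random_params(rng, 3, 2)
        ours = log_joint_density_conditional(params, y, design, cov, spec, signs)
        # oracle: MVN with fixed signs + priors + Bernoulli sign likelihood
        c_matrix = cov.values + RIDGE_FACTOR * np.mean(np.diag(cov.values)) * np.eye(cov.size)
        sigma = np.sqrt(spec.sigma2)
        total = 0.0
        for i in range(y.values.shape[0]):
            total += multivariate_normal.logpdf(
                y.values[i], (signs * params["beta"]) @ design.values[i], c_matrix
            )
        for s in range(3):
            for j in range(2):
                total += truncnorm.logpdf(
                    params["beta"][s, j], -params["a"][j] / sigma, np.inf,
                    loc=params["a"][j], scale=sigma,
                )
                total += np.log(params["pi1"]) if signs[s, j] > 0 else np.log1p(-params["pi1"])
        for j in range(2):
            total += truncnorm.logpdf(params["a"][j], 0.0, np.inf, loc=0.0, scale=1.0)
        total += beta_dist.logpdf(params["pi1"], spec.pi1_alpha, spec.pi1_beta)
        assert ours == pytest.approx(total, abs=1e-8)


class TestPosteriorGradients:
    def finite_difference(self, posterior, q, eps=1e-6):
        num = np.empty_like(q)
        for i in range(q.size):
            qp, qm = q.copy(), q.copy()
            qp[i] += eps
            qm[i] -= eps
            num[i] = (posterior.logp_grad(qp)[0] - posterior.logp_grad(qm)[0]) / (2 * eps)
        return num

    @pytest.mark.parametrize("infer_sigma2", [False, True])
    def test_full_gradient(self, rng, infer_sigma2):
        # moderate tau keeps the relaxation's curvature within finite-difference reach
        y, design, cov, _ = random_problem(rng)
        spec = ModelSpec(tau=0.6, infer_sigma2=infer_sigma2)
        posterior = FullPosterior(y, design, cov, spec)
        for _ in range(10):
            q = posterior.initial_position(rng) + rng.normal(0, 0.2, size=posterior.dim)
            lp, grad = posterior.logp_grad(q)
            assert np.isfinite(lp)
            num = self.finite_difference(posterior, q)
            np.testing.assert_allclose(grad, num, rtol=1e-4, atol=1e-5)

    @pytest.mark.parametrize("infer_sigma2", [False, True])
    def test_conditional_gradient(self, rng, infer_sigma2):
        y, design, cov, _ = random_problem(rng)
        spec = ModelSpec(infer_sigma2=infer_sigma2)
        signs = np.where(rng.uniform(size=(3, 2)) < 0.5, 1.0, -1.0)
        posterior = ConditionalPosterior(y, design, cov, spec, signs)
        for _ in range(10):
            q = posterior.initial_position(rng) + rng.normal(0, 0.2, size=posterior.dim)
            num = self.finite_difference(posterior, q)
            np.testing.assert_allclose(posterior.logp_grad(q)[1], num, rtol=1e-4, atol=1e-5)

    def test_unconstrained_target_is_continuous(self, rng):
        """The HMC target stays finite along a random segment (no support walls)."""
        y, design, cov, spec = random_problem(rng)
        posterior = FullPosterior(y, design, cov, spec)
        q0 = posterior.initial_position(rng)
        q1 = posterior.initial_position(rng)
        for t in np.linspace(0, 1, 25):
            lp, _ = posterior.logp_grad((1 - t) * q0 + t * q1)
            assert np.isfinite(lp)


class TestDomainTypes:
    def test_magnitudes_must_be_positive(self):
        with pytest.raises(ValueError):
            MagnitudeMatrix(np.array([[1.0, -0.1]]))

    def test_global_effects_nonnegative(self):
        with pytest.raises(ValueError):
            GlobalEffects(np.array([-0.5]))

    def test_sign_matrix_consistency(self):
        sm = SignMatrix.from_relaxed(np.array([[0.9, 0.1]]))
        np.testing.assert_array_equal(sm.values, [[1.0, -1.0]])
        with pytest.raises(ValueError):
            SignMatrix(np.array([[0.5]]))
        with pytest.raises(ValueError):
            SignMatrix(np.array([[1.0]]), relaxed=np.array([[0.2]]))

    def test_design_matrix_rejects_zero_column(self):
        with pytest.raises(ValueError, match="zero"):
            DesignMatrix(np.array([[1.0, 0.0], [1.0, 0.0]]), ["a", "b"])

    def test_design_with_intercept(self):
        d = DesignMatrix.with_intercept(np.array([[1.5], [2.5]]), ["x"])
        assert d.covariate_names == ["intercept", "x"]
        assert d.intercept == [True, False]
        np.testing.assert_array_equal(d.values[:, 0], 1.0)

    def test_model_spec_validation(self):
        with pytest.raises(ValueError):
            ModelSpec(tau=0.0)
        with pytest.raises(ValueError):
            ModelSpec(sigma2=-1.0)
        with pytest.raises(ValueError):
            ModelSpec(pi1_alpha=0.0)

    def test_model_spec_config_round_trip(self):
        spec = ModelSpec(tau=0.25, sigma2=0.2, infer_sigma2=True, pi1_alpha=2.0, pi1_beta=3.0, scale_c=1.5)
        assert ModelSpec.from_config(spec.to_config()) == spec

    def test_model_spec_unknown_key(self):
        with pytest.raises(KeyError):
            ModelSpec.from_config("bogus = 1\n")
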