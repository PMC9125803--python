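"""Hierarchical log-ratio regression: likelihood, priors, and joint density.

Model summary, for log-ratio responses y_i (length S-1), covariates x_i
(length p, intercept included as a column of the design matrix):

    y_i ~ MVN((Gamma . B) x_i, c * Sigma)
    beta_{s,j} ~ N+(a_j, sigma2)          (positive-truncated Gaussian)
    a_j ~ N+(0, 1)
    gamma_{s,j} = 2 * delta_{s,j} - 1
    delta_{s,j} = Gumbel-Softmax relaxation of Bernoulli(pi1) at temperature tau
    pi1 ~ Beta(alpha, beta)

``.`` denotes the elementwise product.  The relaxation keeps the sign matrix
differentiable: with Gumbel(0, 1) draws g1, g_neg1,

    delta = sigmoid((logit(pi1) + g1 - g_neg1) / tau)

which at tau -> 0 collapses to an exact Bernoulli(pi1) sign indicator.  The
truncated-Gaussian prior on beta includes its a_j-dependent normalizer
1 / Phi(a_j / sigma); omitting it would bias the global effects.

This module exposes the densities on the natural parameter scale plus the
unconstrained-parameterization posteriors (with analytic gradients) consumed
by the HMC sampler in :mod:`mblr.inference`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import betaln, expit, log_ndtr
from scipy.stats import norm

from mblr.compositional import LogRatioTable
from mblr.phylo import SpeciesCovariance

__all__ = [
    "DesignMatrix",
    "ModelSpec",
    "GlobalEffects",
    "MagnitudeMatrix",
    "SignMatrix",
    "gumbel_softmax_delta",
    "gamma_from_delta",
    "linear_predictor",
    "log_joint_density",
]

_LOG_2PI = np.log(2.0 * np.pi)
RIDGE_FACTOR = 1e-8  # times mean diagonal, added before factorizing c*Sigma


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class DesignMatrix:
    """n x p design; intercept columns are flagged so reports can label them."""

    values: np.ndarray
    covariate_names: list
    intercept: list = field(default_factory=list)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("design matrix must be 2-dimensional")
        if not np.all(np.isfinite(values)):
            raise ValueError("design matrix entries must be finite")
        if np.any(np.all(values == 0, axis=0)):
            raise ValueError("design matrix has an all-zero column")
        names = list(self.covariate_names)
        if len(names) != values.shape[1]:
            raise ValueError("covariate name count does not match column count")
        flags = list(self.intercept) or [bool(np.all(values[:, j] == 1.0)) for j in range(values.shape[1])]
        if len(flags) != values.shape[1]:
            raise ValueError("intercept flag count does not match column count")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "covariate_names", names)
        object.__setattr__(self, "intercept", flags)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.values.shape[1]

    @classmethod
    def with_intercept(cls, values: np.ndarray, covariate_names: Sequence[str]) -> "DesignMatrix":
        """Prepend a column of ones named ``intercept``."""
        values = np.asarray(values, dtype=float)
        ones = np.ones((values.shape[0], 1))
        return cls(
            np.hstack([ones, values]),
            ["intercept"] + list(covariate_names),
            [True] + [False] * values.shape[1],
        )


@dataclass(frozen=True)
class ModelSpec:
    """All prior hyperparameters and the relaxation temperature.

    sigma2 is the shared prior variance of the effect magnitudes; it is held
    fixed unless ``infer_sigma2`` is set, in which case it receives a
    half-Gaussian(0, 1) hyperprior.
    """

    tau: float = 0.02
    sigma2: float = 0.1
    infer_sigma2: bool = False
    pi1_alpha: float = 1.0
    pi1_beta: float = 1.0
    scale_c: float = 1.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")
        if self.pi1_alpha <= 0 or self.pi1_beta <= 0:
            raise ValueError("Beta hyperparameters must be > 0")
        if self.scale_c <= 0:
            raise ValueError("scale_c must be > 0")

    def to_config(self) -> str:
        """Flat ``key = value`` serialization."""
        lines = []
        for key in ("tau", "sigma2", "infer_sigma2", "pi1_alpha", "pi1_beta", "scale_c"):
            lines.append(f"{key} = {getattr(self, key)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config(cls, text: str) -> "ModelSpec":
        kwargs = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key = key.strip()
            raw = raw.strip()
            if key not in cls.__dataclass_fields__:
                raise KeyError(f"unknown model spec key: {key!r}")
            if key == "infer_sigma2":
                kwargs[key] = raw.lower() in ("true", "1", "yes")
            else:
                kwargs[key] = float(raw)
        return cls(**kwargs)


@dataclass(frozen=True)
class GlobalEffects:
    """Per-covariate global effect magnitudes a_j >= 0."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if np.any(values < 0):
            raise ValueError("global effects must be nonnegative")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class MagnitudeMatrix:
    """(S-1) x p strictly positive effect magnitudes beta_{s,j}."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if np.any(values <= 0):
            raise ValueError("magnitudes must be strictly positive")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class SignMatrix:
    """(S-1) x p sign matrix; ``relaxed`` carries the continuous deltas when present."""

    values: np.ndarray
    relaxed: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if not np.all(np.isin(values, (-1.0, 1.0))):
            raise ValueError("hard sign entries must be -1 or +1")
        if self.relaxed is not None:
            relaxed = np.asarray(self.relaxed, dtype=float)
            if relaxed.shape != values.shape:
                raise ValueError("relaxed shape mismatch")
            if np.any(relaxed < 0) or np.any(relaxed > 1):
                raise ValueError("relaxed entries must lie in [0, 1]")
            hard = np.where(relaxed >= 0.5, 1.0, -1.0)
            if not np.array_equal(hard, values):
                raise ValueError("hard signs inconsistent with relaxed deltas")
            object.__setattr__(self, "relaxed", relaxed)
        object.__setattr__(self, "values", values)

    @classmethod
    def from_relaxed(cls, relaxed: np.ndarray) -> "SignMatrix":
        relaxed = np.asarray(relaxed, dtype=float)
        return cls(np.where(relaxed >= 0.5, 1.0, -1.0), relaxed)


# ---------------------------------------------------------------------------
# elementary operations


def gumbel_softmax_delta(pi1, g1, g_neg1, tau: float):
    """Two-class Gumbel-Softmax coordinate.

    delta = exp((log pi1 + g1)/tau) /
            [exp((log pi1 + g1)/tau) + exp((log(1-pi1) + g_neg1)/tau)]

    evaluated as a logistic of the shifted difference, which cannot overflow.
    Accepts scalars or broadcastable arrays.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    pi1 = np.asarray(pi1, dtype=float)
    if np.any(pi1 <= 0) or np.any(pi1 >= 1):
        raise ValueError("pi1 must be strictly inside (0, 1)")
    logit_pi1 = np.log(pi1) - np.log1p(-pi1)
    out = expit((logit_pi1 + np.asarray(g1) - np.asarray(g_neg1)) / tau)
    return float(out) if out.ndim == 0 else out


def gamma_from_delta(delta):
    """Map a relaxed sign delta in [0, 1] to gamma = 2*delta - 1 in [-1, 1]."""
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0) or np.any(delta > 1):
        raise ValueError("delta must lie in [0, 1]")
    out = 2.0 * delta - 1.0
    return float(out) if out.ndim == 0 else out


def linear_predictor(gamma: np.ndarray, beta: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Mean vector mu = (gamma . beta) @ x for a single covariate vector x."""
    gamma = np.asarray(gamma, dtype=float)
    beta = np.asarray(beta, dtype=float)
    x = np.asarray(x, dtype=float)
    if gamma.shape != beta.shape:
        raise ValueError("gamma and beta shapes differ")
    if x.shape != (gamma.shape[1],):
        raise ValueError("covariate vector length does not match coefficient columns")
    return (gamma * beta) @ x


# ---------------------------------------------------------------------------
# covariance plumbing


class CovOps:
    """Cached Cholesky operations for the MVN covariance c*Sigma (plus ridge)."""

    def __init__(self, cov: SpeciesCovariance):
        values = np.asarray(cov.values, dtype=float)
        ridge = RIDGE_FACTOR * float(np.mean(np.diag(values)))
        self.matrix = values + ridge * np.eye(values.shape[0])
        self.factor = cho_factor(self.matrix, lower=True)
        self.log_det = 2.0 * np.sum(np.log(np.diag(self.factor[0])))
        self.size = values.shape[0]

    def solve(self, b: np.ndarray) -> np.ndarray:
        return cho_solve(self.factor, b)

    def mvn_logpdf_sum(self, resid: np.ndarray) -> float:
        """Sum over rows of the centered MVN log-density (resid is n x (S-1))."""
        quad = float(np.sum(resid * self.solve(resid.T).T))
        n = resid.shape[0]
        return -0.5 * (n * self.size * _LOG_2PI + n * self.log_det + quad)


# ---------------------------------------------------------------------------
# joint density (natural scale)


def _gumbel_logpdf_sum(g: np.ndarray) -> float:
    return float(np.sum(-g - np.exp(-g)))


def _beta_logpdf(pi1: float, alpha: float, beta: float) -> float:
    return (alpha - 1.0) * np.log(pi1) + (beta - 1.0) * np.log1p(-pi1) - betaln(alpha, beta)


def _truncnorm_pos_logpdf_sum(beta: np.ndarray, mean: np.ndarray, sigma2: float) -> float:
    """Sum of N+(mean, sigma2) log-densities over a (S-1) x p matrix of magnitudes.

    The normalizer is 1 - Phi(-mean/sigma) = Phi(mean/sigma), which depends on
    the global effect and must stay in the density.
    """
    sigma = np.sqrt(sigma2)
    z2 = (beta - mean) ** 2 / sigma2
    log_norm = log_ndtr(mean / sigma)  # log Phi(a_j / sigma)
    n_rows = beta.shape[0]
    return float(
        np.sum(-0.5 * (_LOG_2PI + np.log(sigma2)) - 0.5 * z2) - n_rows * np.sum(log_norm)
    )


def log_joint_density(
    params: dict,
    data: LogRatioTable,
    design: DesignMatrix,
    cov: SpeciesCovariance,
    spec: ModelSpec,
    *,
    cov_ops: CovOps | None = None,
) -> float:
    """Log of the full-model joint density at natural-scale parameters.

    ``params`` keys: ``a`` (p,), ``beta`` ((S-1) x p), ``g1``/``g_neg1``
    ((S-1) x p Gumbel latents), ``pi1`` scalar, optional ``sigma2`` when the
    spec infers it.  Returns -inf outside the support (beta <= 0, a < 0).
    The result equals the sum of: the MVN likelihood of every sample, the
    positive-truncated Gaussian priors on beta and a (normalizers included),
    the Beta prior on pi1, and the Gumbel(0, 1) densities of the latents.
    """
    a = np.asarray(params["a"], dtype=float)
    beta = np.asarray(params["beta"], dtype=float)
    g1 = np.asarray(params["g1"], dtype=float)
    g_neg1 = np.asarray(params["g_neg1"], dtype=float)
    pi1 = float(params["pi1"])
    sigma2 = float(params["sigma2"]) if spec.infer_sigma2 else spec.sigma2

    if np.any(beta <= 0) or np.any(a < 0) or not (0 < pi1 < 1) or sigma2 <= 0:
        return -np.inf

    ops = cov_ops if cov_ops is not None else CovOps(cov)
    delta = gumbel_softmax_delta(pi1, g1, g_neg1, spec.tau)
    gamma = gamma_from_delta(delta)
    mu = design.values @ (gamma * beta).T
    resid = data.values - mu

    logp = ops.mvn_logpdf_sum(resid)
    logp += _truncnorm_pos_logpdf_sum(beta, a[None, :], sigma2)
    # a_j ~ N+(0, 1): normalizer 1/(1 - Phi(0)) = 2
    logp += float(np.sum(-0.5 * _LOG_2PI - 0.5 * a**2 + np.log(2.0)))
    logp += float(_beta_logpdf(pi1, spec.pi1_alpha, spec.pi1_beta))
    logp += _gumbel_logpdf_sum(g1) + _gumbel_logpdf_sum(g_neg1)
    if spec.infer_sigma2:
        # half-Gaussian(0, 1) hyperprior on sigma2
        logp += float(np.log(2.0) - 0.5 * _LOG_2PI - 0.5 * sigma2**2)
    return float(logp)


def log_joint_density_conditional(
    params: dict,
    data: LogRatioTable,
    design: DesignMatrix,
    cov: SpeciesCovariance,
    spec: ModelSpec,
    signs: np.ndarray,
    *,
    cov_ops: CovOps | None = None,
) -> float:
    """Log joint of the conditional model: Gamma fixed, delta machinery bypassed.

    The fixed signs contribute a Bernoulli(pi1) likelihood term so pi1 remains
    identified; everything else matches the full model.
    """
    a = np.asarray(params["a"], dtype=float)
    beta = np.asarray(params["beta"], dtype=float)
    pi1 = float(params["pi1"])
    sigma2 = float(params["sigma2"]) if spec.infer_sigma2 else spec.sigma2
    signs = np.asarray(signs, dtype=float)

    if np.any(beta <= 0) or np.any(a < 0) or not (0 < pi1 < 1) or sigma2 <= 0:
        return -np.inf

    ops = cov_ops if cov_ops is not None else CovOps(cov)
    mu = design.values @ (signs * beta).T
    resid = data.values - mu

    n_pos = float(np.sum(signs > 0))
    n_neg = float(signs.size - n_pos)

    logp = ops.mvn_logpdf_sum(resid)
    logp += _truncnorm_pos_logpdf_sum(beta, a[None, :], sigma2)
    logp += float(np.sum(-0.5 * _LOG_2PI - 0.5 * a**2 + np.log(2.0)))
    logp += float(_beta_logpdf(pi1, spec.pi1_alpha, spec.pi1_beta))
    logp += n_pos * np.log(pi1) + n_neg * np.log1p(-pi1)
    if spec.infer_sigma2:
        logp += float(np.log(2.0) - 0.5 * _LOG_2PI - 0.5 * sigma2**2)
    return float(logp)


# ---------------------------------------------------------------------------
# unconstrained posteriors with analytic gradients (HMC targets)


class _PosteriorBase:
    """Shared pieces: data, cached covariance solve, spec."""

    def __init__(self, data: LogRatioTable, design: DesignMatrix, cov: SpeciesCovariance, spec: ModelSpec):
        if data.values.shape[0] != design.values.shape[0]:
            raise ValueError("response and design sample counts differ")
        if data.values.shape[1] != cov.size:
            raise ValueError("response dimension does not match covariance size")
        self.y = np.asarray(data.values, dtype=float)
        self.x = np.asarray(design.values, dtype=float)
        self.spec = spec
        self.ops = CovOps(cov)
        self.n, self.s1 = self.y.shape
        self.p = self.x.shape[1]
        self.k = self.s1 * self.p

    # truncated-normal prior pieces shared by both variants ------------------
    def _beta_prior_terms(self, beta, a, sigma2):
        """Returns (logp, dlogp/dbeta, dlogp/da, dlogp/dsigma2)."""
        sigma = np.sqrt(sigma2)
        diff = beta - a[None, :]
        z = a / sigma
        log_phi_cdf = log_ndtr(z)
        # phi(z)/Phi(z), computed in log space for stability at very negative z
        ratio = np.exp(norm.logpdf(z) - log_phi_cdf)
        logp = float(np.sum(-0.5 * (_LOG_2PI + np.log(sigma2)) - 0.5 * diff**2 / sigma2)
                     - self.s1 * np.sum(log_phi_cdf))
        d_beta = -diff / sigma2
        d_a = diff.sum(axis=0) / sigma2 - self.s1 * ratio / sigma
        d_sigma2 = (
            float(np.sum(-0.5 / sigma2 + 0.5 * diff**2 / sigma2**2))
            + self.s1 * float(np.sum(ratio * a)) / (2.0 * sigma2 * sigma)
        )
        return logp, d_beta, d_a, d_sigma2

    def _a_prior(self, a):
        logp = float(np.sum(-0.5 * _LOG_2PI - 0.5 * a**2 + np.log(2.0)))
        return logp, -a

    def _sigma2_prior(self, sigma2):
        logp = float(np.log(2.0) - 0.5 * _LOG_2PI - 0.5 * sigma2**2)
        return logp, -sigma2

    def _likelihood_grad_e(self, effects):
        """MVN log-likelihood and its gradient w.r.t. the signed effect matrix."""
        resid = self.y - self.x @ effects.T
        if not np.all(np.isfinite(resid)):
            # exp-scale magnitudes overflowed along a trajectory: reject
            return -np.inf, np.zeros((self.s1, self.p))
        solved = self.ops.solve(resid.T)  # (S-1) x n
        quad = float(np.sum(resid.T * solved))
        logp = -0.5 * (self.n * self.s1 * _LOG_2PI + self.n * self.ops.log_det + quad)
        grad_e = solved @ self.x  # (S-1) x p
        return logp, grad_e


class FullPosterior(_PosteriorBase):
    """Unconstrained-parameter posterior of the full model.

    Layout of the flat vector q:
      [ua (p) | ub (k) | g1 (k) | g_neg1 (k) | v (1) | us (1 if sigma2 inferred)]
    with a = exp(ua), beta = exp(ub), pi1 = sigmoid(v), sigma2 = exp(us).
    ``logp_grad`` returns the log joint *including* transform Jacobians,
    which is the correct HMC target on the unconstrained space.
    """

    variant = "full"

    def __init__(self, data, design, cov, spec):
        super().__init__(data, design, cov, spec)
        self.dim = self.p + 3 * self.k + 1 + (1 if spec.infer_sigma2 else 0)

    def unpack(self, q: np.ndarray) -> dict:
        p, k, s1 = self.p, self.k, self.s1
        ua = q[:p]
        ub = q[p : p + k].reshape(s1, p)
        g1 = q[p + k : p + 2 * k].reshape(s1, p)
        gn = q[p + 2 * k : p + 3 * k].reshape(s1, p)
        v = q[p + 3 * k]
        out = {
            "a": np.exp(ua),
            "beta": np.exp(ub),
            "g1": g1,
            "g_neg1": gn,
            "pi1": float(expit(v)),
        }
        if self.spec.infer_sigma2:
            out["sigma2"] = float(np.exp(q[p + 3 * k + 1]))
        return out

    def initial_position(self, rng: np.random.Generator, sign_hint: np.ndarray | None = None) -> np.ndarray:
        """Modest random start; ``sign_hint`` biases the Gumbel latents toward given signs."""
        q = np.empty(self.dim)
        p, k = self.p, self.k
        q[:p] = np.log(np.abs(rng.normal(0.5, 0.1, size=p)) + 0.05)  # ua
        q[p : p + k] = np.log(np.abs(rng.normal(0.5, 0.1, size=k)) + 0.05)  # ub
        g1 = rng.gumbel(size=(self.s1, self.p))
        gn = rng.gumbel(size=(self.s1, self.p))
        if sign_hint is not None:
            # shift so that sign(g1 - gn) matches the hint
            gap = g1 - gn
            wrong = np.sign(gap) != np.sign(sign_hint)
            g1 = np.where(wrong, g1 + np.abs(gap) * 2 + 0.5, g1)
        q[p + k : p + 2 * k] = g1.ravel()
        q[p + 2 * k : p + 3 * k] = gn.ravel()
        q[p + 3 * k] = rng.normal(0.0, 0.3)
        if self.spec.infer_sigma2:
            q[-1] = np.log(0.1)
        return q

    def logp_grad(self, q: np.ndarray) -> tuple[float, np.ndarray]:
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            logp, grad = self._logp_grad_impl(q)
        if not np.isfinite(logp):
            return -np.inf, np.zeros(self.dim)
        return logp, grad

    def _logp_grad_impl(self, q: np.ndarray) -> tuple[float, np.ndarray]:
        spec = self.spec
        p, k, s1 = self.p, self.k, self.s1
        ua = q[:p]
        ub = q[p : p + k].reshape(s1, p)
        g1 = q[p + k : p + 2 * k].reshape(s1, p)
        gn = q[p + 2 * k : p + 3 * k].reshape(s1, p)
        v = q[p + 3 * k]
        a = np.exp(ua)
        beta = np.exp(ub)
        pi1 = expit(v)
        if spec.infer_sigma2:
            us = q[-1]
            sigma2 = np.exp(us)
        else:
            sigma2 = spec.sigma2

        tau = spec.tau
        s_arg = (v + g1 - gn) / tau
        delta = expit(s_arg)
        gamma = 2.0 * delta - 1.0

        logp, grad_e = self._likelihood_grad_e(gamma * beta)
        grad_beta = grad_e * gamma
        grad_gamma = grad_e * beta

        lp_beta, d_beta, d_a, d_sigma2 = self._beta_prior_terms(beta, a, sigma2)
        logp += lp_beta
        grad_beta = grad_beta + d_beta
        grad_a = d_a

        lp_a, da_prior = self._a_prior(a)
        logp += lp_a
        grad_a = grad_a + da_prior

        # Beta prior on pi1, including the sigmoid Jacobian, expressed in v
        logp += float(_beta_logpdf(pi1, spec.pi1_alpha, spec.pi1_beta)) + float(
            np.log(pi1) + np.log1p(-pi1)
        )
        grad_v = spec.pi1_alpha * (1.0 - pi1) - spec.pi1_beta * pi1

        # Gumbel(0,1) latents
        logp += _gumbel_logpdf_sum(g1) + _gumbel_logpdf_sum(gn)
        grad_g1 = -1.0 + np.exp(-g1)
        grad_gn = -1.0 + np.exp(-gn)

        # chain rule through gamma = 2*sigmoid((v + g1 - gn)/tau) - 1
        d_gamma_ds = 2.0 * delta * (1.0 - delta) / tau
        pull = grad_gamma * d_gamma_ds
        grad_g1 = grad_g1 + pull
        grad_gn = grad_gn - pull
        grad_v += float(np.sum(pull))

        # log-scale Jacobians for a and beta
        logp += float(np.sum(ua)) + float(np.sum(ub))
        grad_ua = grad_a * a + 1.0
        grad_ub = grad_beta * beta + 1.0

        grad = np.empty(self.dim)
        grad[:p] = grad_ua
        grad[p : p + k] = grad_ub.ravel()
        grad[p + k : p + 2 * k] = grad_g1.ravel()
        grad[p + 2 * k : p + 3 * k] = grad_gn.ravel()
        grad[p + 3 * k] = grad_v
        if spec.infer_sigma2:
            lp_s2, ds2_prior = self._sigma2_prior(sigma2)
            logp += lp_s2 + us  # jacobian
            grad[-1] = (d_sigma2 + ds2_prior) * sigma2 + 1.0
        return float(logp), grad


class ConditionalPosterior(_PosteriorBase):
    """Unconstrained posterior of the conditional model (Gamma fixed).

    Layout: [ua (p) | ub (k) | v (1) | us (1 if sigma2 inferred)].
    """

    def __init__(self, data, design, cov, spec, signs: np.ndarray, variant: str = "conditional"):
        super().__init__(data, design, cov, spec)
        signs = np.asarray(signs, dtype=float)
        if signs.shape != (self.s1, self.p):
            raise ValueError("sign matrix shape must be (S-1) x p")
        if not np.all(np.isin(signs, (-1.0, 1.0))):
            raise ValueError("signs must be -1 or +1")
        self.signs = signs
        self.n_pos = float(np.sum(signs > 0))
        self.n_neg = float(signs.size - self.n_pos)
        self.variant = variant
        self.dim = self.p + self.k + 1 + (1 if spec.infer_sigma2 else 0)

    def unpack(self, q: np.ndarray) -> dict:
        p, k, s1 = self.p, self.k, self.s1
        out = {
            "a": np.exp(q[:p]),
            "beta": np.exp(q[p : p + k].reshape(s1, p)),
            "pi1": float(expit(q[p + k])),
        }
        if self.spec.infer_sigma2:
            out["sigma2"] = float(np.exp(q[p + k + 1]))
        return out

    def initial_position(self, rng: np.random.Generator) -> np.ndarray:
        q = np.empty(self.dim)
        p, k = self.p, self.k
        q[:p] = np.log(np.abs(rng.normal(0.5, 0.1, size=p)) + 0.05)
        q[p : p + k] = np.log(np.abs(rng.normal(0.5, 0.1, size=k)) + 0.05)
        q[p + k] = rng.normal(0.0, 0.3)
        if self.spec.infer_sigma2:
            q[-1] = np.log(0.1)
        return q

    def logp_grad(self, q: np.ndarray) -> tuple[float, np.ndarray]:
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            logp, grad = self._logp_grad_impl(q)
        if not np.isfinite(logp):
            return -np.inf, np.zeros(self.dim)
        return logp, grad

    def _logp_grad_impl(self, q: np.ndarray) -> tuple[float, np.ndarray]:
        spec = self.spec
        p, k, s1 = self.p, self.k, self.s1
        ua = q[:p]
        ub = q[p : p + k].reshape(s1, p)
        v = q[p + k]
        a = np.exp(ua)
        beta = np.exp(ub)
        pi1 = expit(v)
        if spec.infer_sigma2:
            us = q[-1]
            sigma2 = np.exp(us)
        else:
            sigma2 = spec.sigma2

        logp, grad_e = self._likelihood_grad_e(self.signs * beta)
        grad_beta = grad_e * self.signs

        lp_beta, d_beta, d_a, d_sigma2 = self._beta_prior_terms(beta, a, sigma2)
        logp += lp_beta
        grad_beta = grad_beta + d_beta

        lp_a, da_prior = self._a_prior(a)
        logp += lp_a
        grad_a = d_a + da_prior

        logp += float(_beta_logpdf(pi1, spec.pi1_alpha, spec.pi1_beta)) + float(
            np.log(pi1) + np.log1p(-pi1)
        )
        logp += self.n_pos * float(np.log(pi1)) + self.n_neg * float(np.log1p(-pi1))
        grad_v = (
            spec.pi1_alpha * (1.0 - pi1)
            - spec.pi1_beta * pi1
            + self.n_pos * (1.0 - pi1)
            - self.n_neg * pi1
        )

        logp += float(np.sum(ua)) + float(np.sum(ub))
        grad = np.empty(self.dim)
        grad[:p] = grad_a * a + 1.0
        grad[p : p + k] = (grad_beta * beta + 1.0).ravel()
        grad[p + k] = grad_v
        if spec.infer_sigma2:
            lp_s2, ds2_prior = self._sigma2_prior(sigma2)
            logp += lp_s2 + us
            grad[-1] = (d_sigma2 + ds2_prior) * sigma2 + 1.0
        return float(logp), grad
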