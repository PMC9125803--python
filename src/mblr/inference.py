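"""Fitting the full, conditional, and oracle-conditional models by HMC.

The full model samples signs through the Gumbel-Softmax relaxation; the
conditional variant fixes the sign matrix (either estimated by per-taxon
ordinary least squares — the two-step approximation — or supplied from ground
truth for the oracle benchmark) and samples only the magnitudes, global
effects and sign prevalence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mblr.compositional import LogRatioTable
from mblr.hmc import sample_chain
from mblr.model_core import (
    ConditionalPosterior,
    DesignMatrix,
    FullPosterior,
    ModelSpec,
    SignMatrix,
)
from mblr.phylo import SpeciesCovariance

logger = logging.getLogger(__name__)

__all__ = [
    "SamplerConfig",
    "PosteriorSamples",
    "fit_full",
    "fit_conditional",
    "estimate_signs",
    "diagnostics",
    "split_rhat",
    "effective_sample_size",
]


@dataclass(frozen=True)
class SamplerConfig:
    """HMC run settings.  Defaults mirror the benchmark protocol (4 x 8000)."""

    chains: int = 4
    iterations: int = 8000
    warmup_fraction: float = 0.5
    seed: int = 0
    target_accept: float = 0.8
    rhat_threshold: float = 1.01
    max_leapfrog: int = 48
    trajectory_length: float = 1.2

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if not (0 < self.warmup_fraction < 1):
            raise ValueError("warmup fraction must be in (0, 1)")
        if self.n_warmup >= self.iterations:
            raise ValueError("iterations must exceed warmup")

    @property
    def n_warmup(self) -> int:
        return int(self.iterations * self.warmup_fraction)

    @classmethod
    def test_profile(cls, seed: int = 0, **overrides) -> "SamplerConfig":
        """Reduced desk-scale profile: 2 chains x 2000 iterations."""
        kwargs = dict(chains=2, iterations=2000, seed=seed)
        kwargs.update(overrides)
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# convergence statistics


def split_rhat(draws: np.ndarray) -> float:
    """Split R-hat of one scalar parameter, draws shaped (chains, iterations)."""
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2:
        raise ValueError("expected (chains, iterations)")
    n_chains, n_draws = draws.shape
    if n_chains < 1 or n_draws < 4:
        return np.nan
    half = n_draws // 2
    split = np.concatenate([draws[:, :half], draws[:, half : 2 * half]], axis=0)
    m, n = split.shape
    if m < 2:
        return np.nan
    chain_means = split.mean(axis=1)
    chain_vars = split.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = n * chain_means.var(ddof=1)
    if w <= 0:
        return 1.0 if b <= 0 else np.inf
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def effective_sample_size(draws: np.ndarray) -> float:
    """ESS via Geyer's initial monotone positive sequence over chain-averaged autocorrelation."""
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 1:
        draws = draws[None, :]
    m, n = draws.shape
    if n < 4:
        return float(m * n)
    centered = draws - draws.mean(axis=1, keepdims=True)
    max_lag = n - 1
    acov = np.empty((m, max_lag))
    for c in range(m):
        full = np.correlate(centered[c], centered[c], mode="full")[n - 1 :]
        acov[c] = full[:max_lag] / n
    var0 = acov[:, 0].mean()
    if var0 <= 0:
        return float(m * n)
    rho = acov.mean(axis=0) / var0
    # Geyer: sum consecutive pairs while positive, enforce monotone decrease
    t = 1
    sum_rho = 0.0
    prev_pair = np.inf
    while t + 1 < max_lag:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, prev_pair)
        sum_rho += pair
        prev_pair = pair
        t += 2
    ess = m * n / (1.0 + 2.0 * sum_rho)
    return float(min(ess, m * n))


# ---------------------------------------------------------------------------
# posterior container


@dataclass
class PosteriorSamples:
    """Posterior draws plus convergence diagnostics for one fitted model."""

    variant: str  # full | conditional | oracle
    draws: dict  # name -> array, leading dims (chains, kept_draws)
    taxon_ids: list
    covariate_names: list
    rhat: dict = field(default_factory=dict)
    ess: dict = field(default_factory=dict)
    divergence_rate: float = 0.0
    flags: list = field(default_factory=list)
    fixed_signs: np.ndarray | None = None
    config: SamplerConfig | None = None

    # ---- scalar series used for diagnostics and reporting ------------------
    def scalar_series(self) -> dict:
        """Flatten every sampled parameter into named (chains, draws) series."""
        out = {}
        for name, arr in self.draws.items():
            if arr.ndim == 2:
                out[name] = arr
            elif arr.ndim == 3:
                for j in range(arr.shape[2]):
                    out[f"{name}[{self._col_label(name, j)}]"] = arr[:, :, j]
            elif arr.ndim == 4:
                for s in range(arr.shape[2]):
                    for j in range(arr.shape[3]):
                        out[f"{name}[{self.taxon_ids[s]},{self.covariate_names[j]}]"] = arr[:, :, s, j]
        return out

    def _col_label(self, name: str, j: int) -> str:
        return self.covariate_names[j] if name == "a" else str(j)

    # ---- posterior summaries -----------------------------------------------
    def global_effect_means(self) -> np.ndarray:
        """Posterior mean of a_j, one entry per design column."""
        return self.draws["a"].mean(axis=(0, 1))

    def beta_means(self) -> np.ndarray:
        return self.draws["beta"].mean(axis=(0, 1))

    def delta_means(self) -> np.ndarray | None:
        if "delta" not in self.draws:
            return None
        return self.draws["delta"].mean(axis=(0, 1))

    def sign_calls(self) -> np.ndarray:
        """Hard sign per (taxon, covariate): fixed signs, or posterior mean delta thresholded at 0.5."""
        if self.fixed_signs is not None:
            return self.fixed_signs.copy()
        dm = self.delta_means()
        return np.where(dm >= 0.5, 1.0, -1.0)

    def signed_effect_means(self) -> np.ndarray:
        """Posterior mean of gamma * beta per (taxon, covariate)."""
        beta = self.draws["beta"]
        if self.fixed_signs is not None:
            gamma = self.fixed_signs[None, None, :, :]
        else:
            gamma = 2.0 * self.draws["delta"] - 1.0
        return (gamma * beta).mean(axis=(0, 1))

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, series in self.scalar_series().items():
            flat = series.reshape(-1)
            rows.append(
                {
                    "parameter": name,
                    "mean": flat.mean(),
                    "sd": flat.std(ddof=1),
                    "q2.5": np.quantile(flat, 0.025),
                    "q97.5": np.quantile(flat, 0.975),
                    "rhat": self.rhat.get(name, np.nan),
                    "ess": self.ess.get(name, np.nan),
                }
            )
        return pd.DataFrame(rows)

    def to_long_frame(self) -> pd.DataFrame:
        """Tidy draws: chain, iteration, parameter, value."""
        frames = []
        for name, series in self.scalar_series().items():
            m, t = series.shape
            frames.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(m), t),
                        "iteration": np.tile(np.arange(t), m),
                        "parameter": name,
                        "value": series.reshape(-1),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# fitting


def _run_chains(posterior, sc: SamplerConfig, init_fn) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    kept = sc.iterations - sc.n_warmup
    positions = np.empty((sc.chains, kept, posterior.dim))
    accept = np.empty((sc.chains, kept))
    divergent = np.zeros((sc.chains, kept), dtype=bool)
    for chain in range(sc.chains):
        rng = np.random.default_rng([sc.seed, chain])
        q0 = init_fn(rng)
        result = sample_chain(
            posterior.logp_grad,
            q0,
            sc.iterations,
            sc.n_warmup,
            rng,
            target_accept=sc.target_accept,
            trajectory_length=sc.trajectory_length,
            max_leapfrog=sc.max_leapfrog,
        )
        positions[chain] = result.positions
        accept[chain] = result.accept_prob
        divergent[chain] = result.divergent
    return positions, accept, divergent


def _collect(posterior, positions, variant, taxon_ids, covariate_names, sc, divergent, fixed_signs=None):
    n_chains, kept, _ = positions.shape
    s1, p = posterior.s1, posterior.p
    draws: dict[str, np.ndarray] = {
        "a": np.empty((n_chains, kept, p)),
        "beta": np.empty((n_chains, kept, s1, p)),
        "pi1": np.empty((n_chains, kept)),
    }
    if variant == "full":
        draws["delta"] = np.empty((n_chains, kept, s1, p))
    if posterior.spec.infer_sigma2:
        draws["sigma2"] = np.empty((n_chains, kept))
    tau = posterior.spec.tau
    for c in range(n_chains):
        for t in range(kept):
            q = positions[c, t]
            nat = posterior.unpack(q)
            draws["a"][c, t] = nat["a"]
            draws["beta"][c, t] = nat["beta"]
            draws["pi1"][c, t] = nat["pi1"]
            if variant == "full":
                from scipy.special import expit, logit

                v = logit(nat["pi1"])
                draws["delta"][c, t] = expit((v + nat["g1"] - nat["g_neg1"]) / tau)
            if posterior.spec.infer_sigma2:
                draws["sigma2"][c, t] = nat["sigma2"]

    samples = PosteriorSamples(
        variant=variant,
        draws=draws,
        taxon_ids=list(taxon_ids),
        covariate_names=list(covariate_names),
        divergence_rate=float(divergent.mean()),
        fixed_signs=None if fixed_signs is None else np.asarray(fixed_signs, dtype=float),
        config=sc,
    )
    for name, series in samples.scalar_series().items():
        samples.rhat[name] = split_rhat(series) if sc.chains >= 2 else np.nan
        samples.ess[name] = effective_sample_size(series)

    if samples.divergence_rate > 0.10:
        msg = f"{variant} model: {samples.divergence_rate:.1%} divergent transitions"
        samples.flags.append(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=3)
    bad = [n for n, r in samples.rhat.items() if np.isfinite(r) and r > sc.rhat_threshold]
    if bad and sc.chains >= 2:
        msg = f"{variant} model: R-hat above {sc.rhat_threshold} for {len(bad)} parameter(s)"
        samples.flags.append(msg)
        logger.warning(msg)
    return samples


def fit_full(
    y: LogRatioTable,
    design: DesignMatrix,
    cov: SpeciesCovariance,
    spec: ModelSpec,
    sc: SamplerConfig,
) -> PosteriorSamples:
    """Fit the full log-ratio model (signs sampled via Gumbel-Softmax) by HMC.

    Chains are initialized with Gumbel latents biased toward the per-taxon
    least-squares signs; this speeds convergence and does not change the
    stationary distribution.
    """
    posterior = FullPosterior(y, design, cov, spec)
    try:
        hint = estimate_signs(y, design).values
    except ValueError:
        hint = None
    positions, _, divergent = _run_chains(
        posterior, sc, lambda rng: posterior.initial_position(rng, sign_hint=hint)
    )
    return _collect(posterior, positions, "full", y.taxon_ids, design.covariate_names, sc, divergent)


def fit_conditional(
    y: LogRatioTable,
    design: DesignMatrix,
    cov: SpeciesCovariance,
    spec: ModelSpec,
    sc: SamplerConfig,
    signs: SignMatrix,
    *,
    variant: str = "conditional",
) -> PosteriorSamples:
    """Fit the conditional model with the sign matrix held fixed.

    Pass signs from :func:`estimate_signs` for the two-step approximation, or
    the simulation truth for the oracle benchmark (``variant="oracle"``).
    """
    posterior = ConditionalPosterior(y, design, cov, spec, signs.values, variant=variant)
    positions, _, divergent = _run_chains(posterior, sc, posterior.initial_position)
    return _collect(
        posterior,
        positions,
        variant,
        y.taxon_ids,
        design.covariate_names,
        sc,
        divergent,
        fixed_signs=signs.values,
    )


def estimate_signs(y: LogRatioTable, design: DesignMatrix) -> SignMatrix:
    """Two-step sign estimate: per-taxon OLS of y on X, then the coefficient signs.

    A coefficient of exactly zero maps to +1.
    """
    x = design.values
    n, p = x.shape
    if n <= p:
        raise ValueError("need more samples than covariates for least squares")
    if np.linalg.matrix_rank(x) < p:
        raise ValueError("design matrix is rank deficient")
    coef, *_ = np.linalg.lstsq(x, y.values, rcond=None)  # (p, S-1)
    return SignMatrix(signs_from_coefficients(coef.T))


def signs_from_coefficients(coef: np.ndarray) -> np.ndarray:
    """sign() rule of the two-step procedure: -1 for negative, +1 otherwise (zero -> +1)."""
    return np.where(np.asarray(coef, dtype=float) < 0, -1.0, 1.0)


@dataclass(frozen=True)
class ConvergenceReport:
    rhat: dict
    ess: dict
    rhat_available: bool
    threshold: float
    passed: bool
    worst_rhat: float
    message: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": list(self.rhat),
                "rhat": list(self.rhat.values()),
                "ess": [self.ess[k] for k in self.rhat],
            }
        )


def diagnostics(samples: PosteriorSamples, sc: SamplerConfig) -> ConvergenceReport:
    """Per-parameter split R-hat and ESS with an overall pass/fail verdict."""
    series = samples.scalar_series()
    n_chains = next(iter(series.values())).shape[0]
    ess = {name: effective_sample_size(s) for name, s in series.items()}
    if n_chains < 2:
        return ConvergenceReport(
            rhat={name: np.nan for name in series},
            ess=ess,
            rhat_available=False,
            threshold=sc.rhat_threshold,
            passed=False,
            worst_rhat=np.nan,
            message="R-hat unavailable: need at least 2 chains",
        )
    rhat = {name: split_rhat(s) for name, s in series.items()}
    finite = [r for r in rhat.values() if np.isfinite(r)]
    worst = max(finite) if finite else np.nan
    passed = bool(finite) and worst <= sc.rhat_threshold
    return ConvergenceReport(
        rhat=rhat,
        ess=ess,
        rhat_available=True,
        threshold=sc.rhat_threshold,
        passed=passed,
        worst_rhat=worst,
        message="converged" if passed else f"worst R-hat {worst:.4f} exceeds {sc.rhat_threshold}",
    )
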