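"""Synthetic data generation with full ground truth.

The generative chain: random rooted binary tree -> Brownian covariance ->
standard-normal covariates (plus intercept) -> Bernoulli(0.5) signs ->
positive-truncated Gaussian magnitudes around the global effects -> MVN
log-ratios -> proportions -> multinomial counts with 100*S trials per sample.
Every intermediate is retained so each inference variant can be scored
against the truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from mblr.compositional import (
    CountTable,
    LogRatioTable,
    counts_to_proportions,
    inverse_log_ratio,
    log_ratio_transform,
)
from mblr.inference import SamplerConfig, estimate_signs, fit_conditional, fit_full
from mblr.model_core import DesignMatrix, ModelSpec, SignMatrix
from mblr.phylo import PhyloTree, SpeciesCovariance, brownian_covariance, model_covariance, read_newick

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_tree",
    "simulate_dataset",
    "replicate_study",
    "BASELINE_GLOBAL_EFFECTS",
]

# benchmark baseline: intercept plus two covariates with global effects 1, 0.5, 0
BASELINE_GLOBAL_EFFECTS = (1.0, 0.5, 0.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Settings of the generative process; defaults are the benchmark baseline."""

    n: int = 100
    s: int = 10
    p: int = 2  # covariates excluding the intercept
    a: tuple = BASELINE_GLOBAL_EFFECTS  # length p+1, intercept first
    sigma2: float = 0.1
    trials_multiplier: int = 100
    scale_c: float = 1.0
    seed: int = 0
    use_tree: bool = True
    # optional per-species magnitude variances for sensitivity runs; overrides sigma2
    sigma2_by_species: tuple | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need n >= 2 samples")
        if self.s < 2:
            raise ValueError("need S >= 2 species")
        if self.p < 0:
            raise ValueError("p must be >= 0")
        if len(self.a) != self.p + 1:
            raise ValueError(f"true effects must have length p+1 = {self.p + 1}")
        if any(v < 0 for v in self.a):
            raise ValueError("global effects must be nonnegative")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")
        if self.trials_multiplier < 1:
            raise ValueError("trials_multiplier must be >= 1")
        if self.sigma2_by_species is not None and len(self.sigma2_by_species) != self.s - 1:
            raise ValueError("sigma2_by_species must have length S-1")


@dataclass
class SimulationTruth:
    """One simulated dataset with every intermediate of the generative chain."""

    config: SimulationConfig
    tree: PhyloTree | None
    covariance: SpeciesCovariance
    design: DesignMatrix
    gamma: np.ndarray  # (S-1) x (p+1), entries in {-1, +1}
    beta: np.ndarray  # (S-1) x (p+1), > 0
    a: np.ndarray  # (p+1,)
    y: LogRatioTable  # latent log-ratios (pre-count noise)
    counts: CountTable

    def observed_log_ratios(self, pseudocount: float = 0.5) -> LogRatioTable:
        """Log-ratios recomputed from the counts, the quantity a real analysis sees."""
        comp = counts_to_proportions(self.counts, pseudocount=pseudocount)
        return log_ratio_transform(comp, reference_taxon=self.y.reference_taxon)

    def write(self, outdir) -> None:
        """Serialize one replicate: counts TSV, covariates TSV, newick, truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.write(outdir / "counts.tsv")
        pd.DataFrame(
            self.design.values,
            index=self.counts.sample_ids,
            columns=self.design.covariate_names,
        ).to_csv(outdir / "covariates.tsv", sep="\t", index_label="sample_id")
        if self.tree is not None:
            self.tree.write(outdir / "tree.nwk")
        truth = {
            "a": list(map(float, self.a)),
            "beta": self.beta.tolist(),
            "gamma": self.gamma.tolist(),
            "sigma2": self.config.sigma2,
            "seed": self.config.seed,
            "reference_taxon": self.y.reference_taxon,
            "covariate_names": self.design.covariate_names,
            "taxon_ids": self.y.taxon_ids,
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))


def _random_split_newick(labels: list, rng: np.random.Generator) -> str:
    """Recursive random bipartition: uniform split sizes, Uniform(0, 1) branch lengths."""
    if len(labels) == 1:
        return f"{labels[0]}:{rng.uniform():.10f}"
    k = int(rng.integers(1, len(labels)))
    perm = [labels[i] for i in rng.permutation(len(labels))]
    left, right = perm[:k], perm[k:]
    return (
        f"({_random_split_newick(left, rng)},{_random_split_newick(right, rng)})"
        f":{rng.uniform():.10f}"
    )


def simulate_tree(s: int, seed) -> PhyloTree:
    """Random rooted binary tree with ``s`` labeled tips and Uniform(0, 1) branch lengths."""
    if s < 2:
        raise ValueError("need at least 2 tips")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = [f"taxon{i + 1}" for i in range(s)]
    k = int(rng.integers(1, s))
    perm = [labels[i] for i in rng.permutation(s)]
    newick = (
        f"({_random_split_newick(perm[:k], rng)},{_random_split_newick(perm[k:], rng)});"
    )
    return read_newick(newick)


def sample_truncated_magnitudes(
    a: np.ndarray, sigma2, shape: tuple, rng: np.random.Generator
) -> np.ndarray:
    """Exact inverse-CDF draws from N+(a_j, sigma2), broadcast over a (S-1) x (p+1) shape."""
    sigma = np.sqrt(np.asarray(sigma2, dtype=float))
    loc = np.broadcast_to(np.asarray(a, dtype=float)[None, :], shape)
    scale = np.broadcast_to(sigma, shape) if np.ndim(sigma) else np.full(shape, sigma)
    u = rng.uniform(size=shape)
    lower = (0.0 - loc) / scale
    return truncnorm.ppf(u, lower, np.inf, loc=loc, scale=scale)


def simulate_dataset(cfg: SimulationConfig) -> SimulationTruth:
    """Run the full generative chain; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    s1 = cfg.s - 1
    p_total = cfg.p + 1

    taxa = [f"taxon{i + 1}" for i in range(cfg.s)]
    reference = taxa[-1]
    if cfg.use_tree:
        tree = simulate_tree(cfg.s, rng)
        full_cov = brownian_covariance(tree, taxa)
        cov = model_covariance(full_cov, taxa, reference, scale_c=cfg.scale_c)
    else:
        tree = None
        cov = model_covariance(None, taxa, reference, scale_c=cfg.scale_c)

    covariates = rng.normal(size=(cfg.n, cfg.p))
    design = DesignMatrix.with_intercept(covariates, [f"x{j + 1}" for j in range(cfg.p)])

    gamma = np.where(rng.uniform(size=(s1, p_total)) < 0.5, 1.0, -1.0)
    a = np.asarray(cfg.a, dtype=float)
    sigma2 = (
        np.asarray(cfg.sigma2_by_species, dtype=float)[:, None]
        if cfg.sigma2_by_species is not None
        else cfg.sigma2
    )
    beta = sample_truncated_magnitudes(a, sigma2, (s1, p_total), rng)

    mu = design.values @ (gamma * beta).T  # n x (S-1)
    chol = np.linalg.cholesky(
        cov.values + 1e-10 * np.mean(np.diag(cov.values)) * np.eye(s1)
    )
    y_values = mu + rng.normal(size=(cfg.n, s1)) @ chol.T
    sample_ids = [f"sample{i + 1}" for i in range(cfg.n)]
    y = LogRatioTable(y_values, sample_ids, taxa[:-1], reference)

    rho = inverse_log_ratio(y)
    trials = cfg.trials_multiplier * cfg.s
    counts = np.vstack([rng.multinomial(trials, row) for row in rho.values])
    count_table = CountTable(counts, sample_ids, taxa)

    return SimulationTruth(
        config=cfg,
        tree=tree,
        covariance=cov,
        design=design,
        gamma=gamma,
        beta=beta,
        a=a,
        y=y,
        counts=count_table,
    )


def replicate_study(
    cfg: SimulationConfig,
    n_replicates: int,
    variants: tuple = (),
    spec: ModelSpec | None = None,
    sampler: SamplerConfig | None = None,
    pseudocount: float = 0.5,
    fit_on: str = "counts",
):
    """Generate ``n_replicates`` independent datasets (seeds ``cfg.seed + k``) and
    optionally fit the requested model variants on each.

    Returns ``(truths, fits, summary)`` where ``fits[k][variant]`` is the
    posterior (or the exception raised, recorded rather than fatal), and
    ``summary`` tabulates posterior means against truth, one row per
    (replicate, variant, parameter).
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    if fit_on not in ("counts", "latent"):
        raise ValueError("fit_on must be 'counts' or 'latent'")
    from dataclasses import replace as dc_replace

    truths = []
    fits = []
    rows = []
    for k in range(n_replicates):
        rep_cfg = dc_replace(cfg, seed=cfg.seed + k)
        truth = simulate_dataset(rep_cfg)
        truths.append(truth)
        rep_fits = {}
        if variants:
            y = truth.observed_log_ratios(pseudocount) if fit_on == "counts" else truth.y
            rep_spec = spec or ModelSpec(sigma2=cfg.sigma2, scale_c=cfg.scale_c)
            rep_sc = sampler or SamplerConfig.test_profile(seed=rep_cfg.seed)
            rep_sc = dc_replace(rep_sc, seed=rep_cfg.seed)
            for variant in variants:
                try:
                    if variant == "full":
                        fit = fit_full(y, truth.design, truth.covariance, rep_spec, rep_sc)
                    elif variant == "conditional":
                        signs = estimate_signs(y, truth.design)
                        fit = fit_conditional(
                            y, truth.design, truth.covariance, rep_spec, rep_sc, signs
                        )
                    elif variant == "oracle":
                        fit = fit_conditional(
                            y,
                            truth.design,
                            truth.covariance,
                            rep_spec,
                            rep_sc,
                            SignMatrix(truth.gamma),
                            variant="oracle",
                        )
                    else:
                        raise ValueError(f"unknown variant: {variant!r}")
                except Exception as exc:  # noqa: BLE001 - recorded per replicate
                    rep_fits[variant] = exc
                    continue
                rep_fits[variant] = fit
                a_hat = fit.global_effect_means()
                for j, name in enumerate(truth.design.covariate_names):
                    rows.append(
                        {
                            "replicate": k,
                            "variant": variant,
                            "parameter": f"a[{name}]",
                            "truth": truth.a[j],
                            "estimate": a_hat[j],
                        }
                    )
                beta_hat = fit.beta_means()
                for si, taxon in enumerate(truth.y.taxon_ids):
                    for j, name in enumerate(truth.design.covariate_names):
                        rows.append(
                            {
                                "replicate": k,
                                "variant": variant,
                                "parameter": f"beta[{taxon},{name}]",
                                "truth": truth.beta[si, j],
                                "estimate": beta_hat[si, j],
                            }
                        )
        fits.append(rep_fits)
    summary = pd.DataFrame(rows)
    return truths, fits, summary
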