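# mblr — microbiome Bayesian log-ratio regression

`mblr` detects **global** (whole-community) and **taxon-specific** associations
between covariates and microbial composition. Counts are treated as
compositional: proportions are mapped to unconstrained coordinates with a
log-ratio transform against a reference taxon and modeled as multivariate
Gaussian, with the covariance optionally informed by a Brownian-motion model
on a rooted phylogeny. A hierarchical prior shares information across taxa:
each covariate gets a single nonnegative *global effect* that acts as the
prior mean of the strictly positive per-taxon effect magnitudes, while
per-taxon signs are sampled through a Gumbel-Softmax relaxation so the whole
posterior is amenable to gradient-based Hamiltonian Monte Carlo. The sampler
is implemented in pure NumPy with hand-derived analytic gradients (leapfrog
integration, dual-averaging step-size adaptation, diagonal mass estimation).

Model variants:

- **full** — signs sampled jointly with everything else (Gumbel-Softmax);
- **conditional** — two-step approximation: per-taxon OLS fixes the signs,
  then magnitudes/global effects are sampled conditionally;
- **oracle** — conditional with signs fixed at simulation ground truth
  (benchmark upper bound; available through the Python API).

## Layout

| module | contents |
|---|---|
| `mblr.compositional` | count/proportion/log-ratio tables, transform + inverse |
| `mblr.phylo` | newick trees, Brownian covariance, reference-dropped model covariance |
| `mblr.model_core` | priors, joint log-density, analytic-gradient posteriors |
| `mblr.hmc` | the HMC engine |
| `mblr.inference` | `fit_full`, `fit_conditional`, `estimate_signs`, R-hat/ESS diagnostics |
| `mblr.simulator` | synthetic-data generator with full ground truth, replicate harness |
| `mblr.cli` | `mblr simulate / fit / report / rerun` |

## CLI

```bash
# simulate 20 replicate datasets (counts, covariates, tree, truth per replicate)
mblr simulate --config sim.json --out sims/ --replicates 20 --seed 1

# fit the full model to one dataset
mblr fit --counts sims/rep001/counts.tsv --covariates sims/rep001/covariates.tsv \
         --tree sims/rep001/tree.nwk --out fit/ \
         --chains 4 --iterations 8000 --seed 1

# two-step conditional model, no tree (identity covariance)
mblr fit --counts counts.tsv --covariates covs.tsv --out fit/ --variant conditional

# posterior report: global-effect density grid + ranked signed taxon effects
mblr report --posterior fit/ --out report/ --top-k 10

# re-execute any run from its manifest
mblr rerun fit/manifest.json --out fit_again/
```

A simulate config is a JSON object with any of `n`, `s`, `p`, `a` (length
p+1, intercept effect first), `sigma2`, `trials_multiplier`, `scale_c`,
`use_tree`, `sigma2_by_species`. Key flags for `fit`: `--variant
{full,conditional}`, `--reference-taxon` (default: last counts column),
`--pseudocount` (default 0.5, added to every cell), `--tau` (relaxation
temperature, default 0.02), `--scale-c`, `--sigma2` / `--infer-sigma2`,
`--chains`, `--iterations`, `--seed`.

Outputs are TSV with fixed column orders: `posterior.tsv` (chain, iteration,
parameter, value), `summary.tsv` (parameter, mean, sd, q2.5, q97.5, rhat,
ess), `diagnostics.tsv` (parameter, rhat, ess), `global_effect_density.tsv`
(covariate, a, density), `species_effects.tsv` (taxon by covariate posterior
mean of sign x magnitude), plus a `manifest.json` sufficient to reproduce the
run bit-for-bit (given single-threaded execution).

Sample labels shared by counts and covariates are intersected (with a logged
warning) when the tables disagree; taxa present in the counts but missing
from the tree are a hard error, since silently pruning them would change the
covariance.

## Notes

- The inverse log-ratio uses the self-consistent normalization
  `rho_ref = 1/(1 + sum_s exp(y_s))`, which is the unique choice satisfying
  both the unit-sum constraint and `rho_s = rho_ref * exp(y_s)`.
- The truncated-Gaussian prior on magnitudes includes its mean-dependent
  normalizing constant `1/Phi(a_j/sigma)`; dropping it would bias the global
  effects upward.
- Zeros are handled by a pseudocount added to every cell before forming
  proportions; there is no explicit zero-inflation model.
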