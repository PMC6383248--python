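# mcpr-sae

Small-area estimation of modern contraceptive prevalence (mCPR) from
multi-round household survey microdata, using a Bayesian hierarchical
logistic model with temporally correlated area effects.

## The problem

National household surveys are powered for national (and sometimes
first-level regional) estimates, but family-planning programs need
prevalence estimates for subnational areas and for *change over time* at
those levels. The design-based "direct" estimate for a small area — users
divided by sample size — is unbiased but extremely noisy when an area
contributes only a handful of sampling clusters per round, and differencing
two noisy direct estimates makes the change estimate noisier still.

This package implements the standard small-area remedy: a hierarchical
model that pools information across areas (through a covariate regression
surface) and across survey rounds (through serially correlated area
effects), and reports every quantity with a full posterior distribution, so
that subnational levels *and* round-to-round changes come with honest
uncertainty intervals.

## The model

For woman *i* in area *k* at survey round *t*, with modern-contraceptive
use indicator `y_ikt` and covariate row `x_ikt`:

```
y_ikt ~ Bernoulli(P_ikt)
logit(P_ikt) = x_ikt' beta + u_kt
u_k1 ~ N(0, sigma^2 / (1 - rho^2))
u_kt = rho * u_{k,t-1} + N(0, sigma^2),   t = 2..T
```

- `x_ikt` contains round-specific intercepts (one indicator per round, no
  global intercept) plus individual covariates: residence, schooling,
  wealth quintile, age, cohabitation, recent sexual activity, health-worker
  contact, exposure to family-planning messaging, fertility intention,
  parity, child survival, and distance to a health facility.
- `u_kt` is a stationary first-order autoregressive (AR(1)) effect per area
  (enumeration area or region), which carries information between rounds.
- Priors: `beta ~ N(0, 5^2)` per component, `sigma ~ HalfNormal(1)`,
  `rho ~ Uniform(-1, 1)`.

Posterior sampling uses a Pólya-Gamma data-augmentation Gibbs sampler
(exact, no tuning): conditional on the augmentation variables, `(beta, u)`
is jointly Gaussian and is drawn in one block; `sigma` and `rho` are
updated by slice sampling, with an ancillarity–sufficiency interweaving
step for `sigma` that keeps mixing fast even when areas are data-sparse.
Multiple chains are run from over-dispersed starts and convergence is
checked with rank-normalized split R-hat and effective sample size.

Any posterior summary is computed from the draws: area/regional/national
mCPR per round (weighted means of the per-draw probabilities), draw-wise
change posteriors between rounds (correctly accounting for the serial
correlation of estimates across rounds), and probabilities of exceeding
programmatic targets.

## Worked example

The package ships a synthetic-data generator with known truth, so the whole
pipeline can be exercised without access to restricted survey microdata:

```python
import numpy as np
from mcpr_sae import (
    GeneratorConfig, SamplerConfig, aggregate_mcpr, build_design,
    change_posterior, default_covariate_spec, fit, generate_dataset, predict_p,
)

# 4 regions x 5 EAs, 30 women per EA per round, 4 survey rounds
config = GeneratorConfig(n_regions=4, eas_per_region=5,
                         women_per_ea_per_round=30, T=4, seed=20)
records, truth = generate_dataset(config)
print(f"{len(records)} woman-rounds, {records['ea_id'].nunique()} EAs")

spec = default_covariate_spec()
post = fit(records, spec, SamplerConfig(chains=2, warmup=500, draws=1000, seed=21))
design = build_design(records, spec, transforms=post.transforms,
                      area_ids=post.area_ids, rounds=post.rounds)
P = predict_p(post, design)

r1 = aggregate_mcpr(P, records, "national", 1)
r4 = aggregate_mcpr(P, records, "national", 4)
print(f"round 1 mCPR: {r1.point:.3f} (95% UI {r1.ui_lower:.3f}-{r1.ui_upper:.3f}),"
      f" truth {truth.true_mcpr(None, 1, records):.3f}")
print(f"round 4 mCPR: {r4.point:.3f} (95% UI {r4.ui_lower:.3f}-{r4.ui_upper:.3f}),"
      f" truth {truth.true_mcpr(None, 4, records):.3f}")
change = change_posterior(r1, r4)
print(f"round 1 -> 4 change: {change.median_change:+.3f} "
      f"(95% UI {change.ui_lower:+.3f} to {change.ui_upper:+.3f}), "
      f"P(increase) = {np.mean(change.draws > 0):.3f}")
print(f"rho posterior median: {np.median(post.rho_flat):.2f} (truth {truth.rho_true})")
```

Output (about a minute on one CPU):

```
2400 woman-rounds, 20 EAs
round 1 mCPR: 0.116 (95% UI 0.094-0.142), truth 0.127
round 4 mCPR: 0.230 (95% UI 0.200-0.263), truth 0.249
round 1 -> 4 change: +0.113 (95% UI +0.073 to +0.152), P(increase) = 1.000
rho posterior median: 0.76 (truth 0.6)
```

Both round-level truths fall inside their 95% intervals, and the change
posterior cleanly detects the simulated rise in prevalence.

## Command-line interface

The same pipeline is available as a CLI (`mcpr-sae` or `python -m
mcpr_sae.cli`):

```bash
mcpr-sae simulate --config cfg.yaml --seed 3 --out sim/       # dataset + truth
mcpr-sae fit      --data sim/dataset.csv --covariates sim/covariates.yaml \
                  --out fit/ --chains 2 --seed 9              # draws + convergence
mcpr-sae estimate --data sim/dataset.csv --covariates sim/covariates.yaml \
                  --out direct.csv                            # direct estimates
mcpr-sae report   --data sim/dataset.csv --covariates sim/covariates.yaml \
                  --out report/ --chains 2 --seed 9           # full pipeline
```

`report` writes region-by-round mCPR and change tables, direct-estimate
comparators, shrinkage and standardized-residual diagnostics, a convergence
table, and a metadata file with the input data hash, seed and library
versions.

## Reproduction

```bash
# unit, property and acceptance tests (the acceptance tests include a
# 50-replicate parameter-recovery study; allow ~10 minutes)
python -m pytest -o addopts= -p no:cacheprovider -q tests/

# end-to-end run on the default synthetic study; writes headline
# quantities as JSON
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All randomness is controlled by explicit seeds; identical seeds give
bit-identical synthetic data and identical retained draws.

## Layout

- `src/mcpr_sae/data_model.py` — record schema, covariate specification, IO
- `src/mcpr_sae/simulate.py` — synthetic survey generator with known truth
- `src/mcpr_sae/direct.py` — design-based direct estimators
- `src/mcpr_sae/model.py` — hierarchical model and Gibbs sampler
- `src/mcpr_sae/polyagamma.py` — exact Pólya-Gamma sampler (numba)
- `src/mcpr_sae/aggregate.py` — posterior aggregation and change posteriors
- `src/mcpr_sae/diagnostics.py` — shrinkage, residual and convergence checks
- `src/mcpr_sae/cli.py` — command-line pipeline
- `docs/methods.md` — full methods note
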