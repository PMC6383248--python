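# Methods

This note describes the estimators and algorithms implemented in `mcpr_sae`.

## 1. Data structure

The unit of analysis is a woman-round record with nested identifiers
`country_id > region_id > ea_id` (EA = enumeration area, the primary
sampling cluster), a round label `round`, a binary outcome `y` (modern
contraceptive use), a survey weight, and individual covariates. Repeated
survey rounds sample fresh women within the same geography; areas are
linked across rounds only through their random effects, not through panel
observation of individuals. Nesting is validated on load (an EA must belong
to exactly one region), and EAs missing from some rounds are profiled and
can be filtered.

## 2. Direct estimation

Design-based comparators, using only a unit's own sample:

- **EA level.** The unweighted ratio users/n with a Wilson score interval.
  EA samples are small, so the Wilson interval is preferred to the Wald
  interval, which degenerates at 0 and 1.
- **Region and national level.** The survey-weighted proportion
  `p = sum(w y) / sum(w)` with a Taylor-linearization variance clustered on
  EAs: with cluster score totals `z_c = sum_{i in c} w_i (y_i - p)`,
  `Var(p) = m/(m-1) * sum_c z_c^2 / (sum w)^2` over `m` clusters. The 95%
  interval is a Wald interval on the logit scale, back-transformed so it
  respects [0, 1]. With a single cluster the variance falls back to the
  woman-level form and the estimate is flagged unclustered.

## 3. Hierarchical model

For woman `i` in area `k` at round `t`:

```
y_ikt ~ Bernoulli(P_ikt),   logit(P_ikt) = x_ikt' beta + u_kt
```

The design row `x_ikt` has one indicator per round (round-specific
intercepts; no global intercept) followed by the individual covariates.
Categorical covariates are dummy-coded against a reference level;
continuous covariates are standardized using training-data moments that are
stored with the fit and re-applied to any new data.

Area effects follow a stationary AR(1) process per area:

```
u_k1 ~ N(0, sigma^2 / (1 - rho^2))
u_kt = rho u_{k,t-1} + eps_kt,  eps_kt ~ N(0, sigma^2)
```

so the prior precision of `u_k` is tridiagonal and the joint density is
available in closed form. The effect level is configurable (`ea` or
`region`); the EA level is the default.

Priors: `beta_j ~ N(0, 5^2)`, `sigma ~ HalfNormal(1)`,
`rho ~ Uniform(-1, 1)`.

## 4. Posterior computation

Sampling uses Pólya-Gamma (PG) data augmentation. Introducing
`omega_i ~ PG(1, eta_i)` per observation makes the Bernoulli-logit
likelihood conditionally Gaussian in `eta`: with `kappa_i = y_i - 1/2`, the
full conditional of the stacked coefficient vector `(beta, u)` is
multivariate normal with precision `A' Omega A + P0`, where `A = [X, Z]`
(Z the sparse cell-incidence matrix), `Omega = diag(omega)` and `P0` the
block prior precision (`I/25` for beta; `kron(I_K, Q_AR1(rho)) / sigma^2`
for u). One Gibbs sweep draws:

1. `omega_i | eta_i` — exact PG(1, z) draws by Devroye's alternating-series
   rejection sampler (numba-compiled; no truncation error);
2. `(beta, u) | omega, rho, sigma` — one joint Cholesky draw;
3. `log sigma | u, rho` — slice sampling (stepping-out and shrinkage);
4. `rho | u, sigma` — slice sampling on (-1, 1) including the stationary
   Jacobian term `(K/2) log(1 - rho^2)`;
5. an ancillarity–sufficiency interweaving step for `sigma`: holding the
   non-centered effects `u/sigma` fixed, `log sigma` is re-sampled against
   the *likelihood* plus prior, then `u` is rescaled. Steps 3 and 5
   together break the strong coupling between `sigma` and `u` that slows
   centered-only samplers when cells are data-sparse.

There are no tuning parameters and every step is exact or a valid slice
update, so the chain targets the exact posterior. Multiple chains start
from over-dispersed initial values; seeds are managed with `SeedSequence`
spawning so that chains, replicates and components are independent and
reproducible. Convergence is summarized with rank-normalized split R-hat
and bulk effective sample size for every parameter (via `arviz`), with
warn/fail thresholds at 1.05/1.1 and a minimum ESS of 100.

## 5. Aggregation and change

Given retained draws `{beta^(s), u^(s)}`, per-draw probabilities
`P_i^(s) = expit(x_i' beta^(s) + u^(s)_kt)` are aggregated as weighted
means over any domain (EA-round, region-round, national-round):

```
mCPR_d^(s) = sum_{i in d} w_i P_i^(s) / sum_{i in d} w_i
```

Point estimates are posterior medians; uncertainty intervals are 95%
equal-tailed quantiles of the draws. Change between rounds is computed
**draw-wise**, `Delta^(s) = mCPR_{t1}^(s) - mCPR_{t0}^(s)`, which preserves
the posterior correlation between rounds induced by shared `beta` and the
AR(1) effects; the reported change is the median of `Delta^(s)`, which in
general differs from the difference of the two round medians when the
posteriors are skewed. Target probabilities are posterior tail
probabilities, `P(mCPR_d > target) = mean_s 1{mCPR_d^(s) > target}`.

Predictions for areas absent from the fit draw their effects from the
stationary AR(1) prior per posterior draw, which correctly widens their
intervals.

## 6. Diagnostics

- **Shrinkage tables** compare, per unit-round: the direct estimate and its
  interval, the model estimate and its interval, the covariate-only
  regression prediction (effects zeroed), the absolute shrinkage
  `|model - direct|`, and the interval-width ratio. Model estimates shrink
  noisy direct estimates toward the regression surface, more strongly for
  smaller samples, and carry narrower intervals.
- **Standardized residuals (Z-values).** For each unit-round, the observed
  user count is compared with its posterior-predictive distribution. By
  default the unit's random effect is integrated over its stationary AR(1)
  prior (redrawn per posterior draw of `rho, sigma`): under a correctly
  specified model the resulting Z-values are approximately standard normal
  across units, giving a calibrated outlier diagnostic. Conditioning on the
  unit's own fitted effect instead recenters the predictive on the unit's
  own data and deflates the residuals, which destroys the diagnostic's
  power; it remains available as an option. Predictive moments come either
  from the analytic decomposition
  `var = E_s[sum_i P_i (1-P_i)] + Var_s[sum_i P_i]` or from simulated
  counts; the two routes agree up to Monte-Carlo error.
- **Convergence report** as described in section 4.

## 7. Synthetic data generator

The generator draws nested geography (regions, EAs), woman-level covariates
from simple fixed laws, AR(1) area effects with configured `(rho, sigma)`,
and outcomes from the exact model likelihood, using the same design-matrix
construction as the fitter so that generated coefficients are directly
comparable to posterior summaries. It returns the record table plus a truth
object containing `beta`, `rho`, `sigma`, the realized `u_kt`, the
woman-level `P_ikt`, and true weighted mCPR for any domain — enabling
parameter-recovery, coverage, shrinkage and residual-calibration studies
with known answers. Defaults produce a five-country-style survey: 10
regions, 94 EAs, 40 women per EA per round, 4 rounds, with prevalence
rising over rounds. Identical configurations and seeds give bit-identical
datasets.
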