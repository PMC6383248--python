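"""Bayesian hierarchical logistic model for small-area prevalence.

The model is a woman-level logistic regression with round-specific
intercepts and temporally correlated area random effects:

    Y_ikt | P_ikt ~ Bernoulli(P_ikt)
    logit(P_ikt)  = x_ikt' beta + u_kt
    u_k.          ~ stationary AR(1): u_k1 ~ N(0, sigma^2/(1-rho^2)),
                    u_kt = rho u_k,t-1 + N(0, sigma^2)

where k indexes areas (enumeration areas by default, regions optionally)
and t survey rounds. Default priors are weakly informative on the logit
scale: beta_j ~ N(0, 5^2), sigma ~ HalfNormal(1), rho ~ Uniform(-1, 1).

Posterior sampling uses Pólya-Gamma data augmentation (Polson, Scott &
Windle 2013): given auxiliary omega_i ~ PG(1, eta_i), the conditional for
(beta, u) is jointly Gaussian and is drawn exactly in one block;
(rho, sigma) are updated by univariate slice sampling. The sampler is
seeded and reproducible for a given numpy/numba version.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.special import expit

from .data_model import CovariateSpec
from .polyagamma import pg_draw

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrix",
    "ModelParams",
    "PriorConfig",
    "SamplerConfig",
    "PosteriorDraws",
    "EncodingError",
    "build_design",
    "log_likelihood",
    "log_prior",
    "fit",
    "predict_p",
]


class EncodingError(ValueError):
    """A categorical value not present in the covariate specification."""


@dataclass
class DesignMatrix:
    """Encoded design aligned row-for-row with the (complete-case) records.

    Carries the area/round index of every row so the linear predictor
    x'beta + u_kt can be assembled, plus the fitted continuous-covariate
    transforms for reuse at prediction time.
    """

    X: np.ndarray  # (n, p) float64
    columns: list[str]
    area_ids: list[str]  # ordered area labels; u rows follow this order
    rounds: list[int]  # ordered observed rounds; u columns follow this order
    area_index: np.ndarray  # (n,) int, position into area_ids
    round_index: np.ndarray  # (n,) int, position into rounds
    transforms: dict  # continuous covariate name -> (mean, sd)
    effect_level: str  # "ea" or "region"
    records: pd.DataFrame  # validated complete-case rows the design was built from

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def T(self) -> int:
        return len(self.rounds)

    @property
    def K(self) -> int:
        return len(self.area_ids)

    @property
    def cell_index(self) -> np.ndarray:
        """Flat area-major cell index k*T + t for every row."""
        return self.area_index * self.T + self.round_index

    @property
    def y(self) -> np.ndarray:
        return self.records["y"].to_numpy(dtype=np.float64)


@dataclass
class ModelParams:
    beta: np.ndarray  # (p,)
    u: np.ndarray  # (K, T)
    rho: float
    sigma: float


@dataclass
class PriorConfig:
    """Default weakly-informative priors; all overridable."""

    beta_sd: float = 5.0
    sigma_scale: float = 1.0  # HalfNormal scale for the AR(1) innovation sd
    # rho prior is Uniform(-1, 1)


@dataclass
class SamplerConfig:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    rhat_warn: float = 1.05
    ess_warn: float = 100.0


def build_design(
    records: pd.DataFrame,
    specs: Sequence[CovariateSpec],
    effect_level: str = "ea",
    transforms: dict | None = None,
    area_ids: Sequence[str] | None = None,
    rounds: Sequence[int] | None = None,
) -> DesignMatrix:
    """Encode records into the model design matrix.

    Rows with any missing covariate are dropped (complete-case) with the
    count logged. Categorical covariates are dummy-coded against their
    reference level; continuous covariates with ``standardize`` are centered
    and scaled using the build rows, and the transform is stored so the same
    scaling can be reused at prediction time (pass ``transforms``).
    """
    if effect_level not in ("ea", "region"):
        raise ValueError("effect_level must be 'ea' or 'region'")
    cov_names = [s.name for s in specs]
    df = records.dropna(subset=[c for c in cov_names if c in records.columns])
    n_dropped = len(records) - len(df)
    if n_dropped:
        logger.info("dropped %d rows with missing covariates (complete-case)", n_dropped)
    df = df.reset_index(drop=True)

    rnds = sorted(int(r) for r in df["round"].unique()) if rounds is None else list(rounds)
    rpos = {r: i for i, r in enumerate(rnds)}
    unseen_rounds = set(int(r) for r in df["round"].unique()) - set(rnds)
    if unseen_rounds:
        raise EncodingError(f"rounds {sorted(unseen_rounds)} not in the design rounds {rnds}")
    round_index = df["round"].map(rpos).to_numpy(dtype=np.int64)

    cols: list[np.ndarray] = []
    names: list[str] = []
    for r in rnds:
        cols.append((df["round"].to_numpy() == r).astype(np.float64))
        names.append(f"round_{r}")

    fitted: dict = dict(transforms) if transforms else {}
    reuse = transforms is not None
    for s in specs:
        vals = df[s.name]
        if s.kind == "binary":
            v = pd.to_numeric(vals).to_numpy(dtype=np.float64)
            if not np.isin(v, (0.0, 1.0)).all():
                raise EncodingError(f"binary covariate {s.name!r} has values outside {{0,1}}")
            cols.append(v)
            names.append(s.name)
        elif s.kind == "categorical":
            observed = set(vals.astype(str).unique())
            unknown = observed - set(s.levels)
            if unknown:
                raise EncodingError(
                    f"covariate {s.name!r} has level(s) {sorted(unknown)} not in spec"
                )
            for lev in s.levels:
                if lev == s.reference_level:
                    continue
                cols.append((vals.astype(str) == lev).to_numpy(dtype=np.float64))
                names.append(f"{s.name}[{lev}]")
        else:  # continuous
            v = pd.to_numeric(vals).to_numpy(dtype=np.float64)
            if s.standardize:
                if reuse and s.name in fitted:
                    mu, sd = fitted[s.name]
                else:
                    mu, sd = float(v.mean()), float(v.std(ddof=0))
                    sd = sd if sd > 0 else 1.0
                    fitted[s.name] = (mu, sd)
                v = (v - mu) / sd
            cols.append(v)
            names.append(s.name)

    X = np.column_stack(cols) if cols else np.empty((len(df), 0))

    area_col = "ea_id" if effect_level == "ea" else "region_id"
    if area_ids is None:
        aids = sorted(df[area_col].astype(str).unique())
    else:
        aids = [str(a) for a in area_ids]
    apos = {a: i for i, a in enumerate(aids)}
    try:
        area_index = df[area_col].astype(str).map(apos).to_numpy(dtype=np.int64)
    except (ValueError, TypeError):
        raise EncodingError("records contain areas absent from the supplied area_ids")

    return DesignMatrix(
        X=np.ascontiguousarray(X),
        columns=names,
        area_ids=aids,
        rounds=rnds,
        area_index=area_index,
        round_index=round_index,
        transforms=fitted,
        effect_level=effect_level,
        records=df,
    )


def _linear_predictor(params_beta: np.ndarray, u: np.ndarray, design: DesignMatrix) -> np.ndarray:
    return design.X @ params_beta + u[design.area_index, design.round_index]


def log_likelihood(params: ModelParams, design: DesignMatrix, y: np.ndarray | None = None) -> float:
    """Bernoulli log-likelihood sum_i [y_i eta_i - log(1 + e^{eta_i})]."""
    y = design.y if y is None else np.asarray(y, dtype=np.float64)
    eta = _linear_predictor(np.asarray(params.beta, dtype=np.float64), params.u, design)
    if y.shape[0] != eta.shape[0]:
        raise ValueError(f"y has {y.shape[0]} entries for {eta.shape[0]} design rows")
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _ar1_quad(u: np.ndarray, rho: float) -> float:
    """Quadratic form Q(u, rho) of the stationary AR(1) density (sigma = 1)."""
    first = (1.0 - rho * rho) * np.sum(u[:, 0] ** 2)
    if u.shape[1] > 1:
        resid = u[:, 1:] - rho * u[:, :-1]
        return float(first + np.sum(resid ** 2))
    return float(first)


def ar1_log_density(u: np.ndarray, rho: float, sigma: float) -> float:
    """Log density of K independent stationary AR(1) paths of length T."""
    if abs(rho) >= 1.0 or sigma <= 0.0:
        return -np.inf
    K, T = u.shape
    q = _ar1_quad(u, rho)
    return (
        -0.5 * K * T * math.log(2.0 * math.pi)
        - K * T * math.log(sigma)
        + 0.5 * K * math.log(1.0 - rho * rho)
        - q / (2.0 * sigma ** 2)
    )


def log_prior(params: ModelParams, priors: PriorConfig | None = None) -> float:
    """Joint log prior of (beta, u, rho, sigma) under the default family."""
    priors = priors or PriorConfig()
    rho, sigma = float(params.rho), float(params.sigma)
    if abs(rho) >= 1.0 or sigma <= 0.0:
        return -np.inf
    beta = np.asarray(params.beta, dtype=np.float64)
    s2 = priors.beta_sd ** 2
    lp = -0.5 * beta.size * math.log(2.0 * math.pi * s2) - np.sum(beta ** 2) / (2.0 * s2)
    # HalfNormal(sigma_scale) on sigma
    ss = priors.sigma_scale
    lp += 0.5 * math.log(2.0 / math.pi) - math.log(ss) - sigma ** 2 / (2.0 * ss ** 2)
    # Uniform(-1, 1) on rho
    lp += -math.log(2.0)
    lp += ar1_log_density(np.asarray(params.u, dtype=np.float64), rho, sigma)
    return float(lp)


# ---------------------------------------------------------------------------
# posterior container


@dataclass
class PosteriorDraws:
    """Retained MCMC draws, shaped (chains, draws_per_chain, ...)."""

    beta: np.ndarray  # (C, D, p)
    u: np.ndarray  # (C, D, K, T)
    rho: np.ndarray  # (C, D)
    sigma: np.ndarray  # (C, D)
    columns: list[str]
    area_ids: list[str]
    rounds: list[int]
    transforms: dict
    effect_level: str
    seed: int
    warmup: int
    n_chains: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_chains = self.beta.shape[0]

    @property
    def S(self) -> int:
        """Total number of retained draws across chains."""
        return self.beta.shape[0] * self.beta.shape[1]

    @property
    def beta_flat(self) -> np.ndarray:
        return self.beta.reshape(self.S, -1)

    @property
    def u_flat(self) -> np.ndarray:
        return self.u.reshape(self.S, *self.u.shape[2:])

    @property
    def rho_flat(self) -> np.ndarray:
        return self.rho.reshape(self.S)

    @property
    def sigma_flat(self) -> np.ndarray:
        return self.sigma.reshape(self.S)

    def to_arviz(self):
        import arviz as az

        return az.from_dict(
            posterior={
                "beta": self.beta,
                "u": self.u,
                "rho": self.rho,
                "sigma": self.sigma,
            },
            coords={
                "coef": self.columns,
                "area": self.area_ids,
                "round": self.rounds,
            },
            dims={"beta": ["coef"], "u": ["area", "round"]},
        )

    def save(self, path) -> None:
        """Persist draws as a long-format CSV (chain, draw, parameter, value)."""
        rows = []
        C, D, p = self.beta.shape
        names = (
            [f"beta[{c}]" for c in self.columns]
            + [f"u[{a},{r}]" for a in self.area_ids for r in self.rounds]
            + ["rho", "sigma"]
        )
        flat = np.concatenate(
            [
                self.beta.reshape(C, D, -1),
                self.u.reshape(C, D, -1),
                self.rho[..., None],
                self.sigma[..., None],
            ],
            axis=2,
        )
        for c in range(C):
            df = pd.DataFrame(flat[c], columns=names)
            df.insert(0, "draw", np.arange(D))
            df.insert(0, "chain", c)
            rows.append(df)
        pd.concat(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# slice sampler (Neal 2003, stepping-out + shrinkage)


def _slice_sample(x0, logf, rng, w=0.5, max_steps=50, lower=-np.inf, upper=np.inf):
    f0 = logf(x0)
    logy = f0 - rng.standard_exponential()
    L = x0 - w * rng.random()
    R = L + w
    j = int(max_steps * rng.random())
    k = max_steps - 1 - j
    while j > 0 and L > lower and logf(max(L, lower)) > logy:
        L -= w
        j -= 1
    while k > 0 and R < upper and logf(min(R, upper)) > logy:
        R += w
        k -= 1
    L, R = max(L, lower), min(R, upper)
    for _ in range(200):
        x1 = L + (R - L) * rng.random()
        if logf(x1) > logy:
            return x1
        if x1 < x0:
            L = x1
        else:
            R = x1
    return x0  # pathological; keep current state


# ---------------------------------------------------------------------------
# Gibbs sampler


def _ar1_precision(T: int, rho: float) -> np.ndarray:
    """Precision of a stationary AR(1) path of length T with unit innovation sd."""
    M = np.zeros((T, T))
    if T == 1:
        M[0, 0] = 1.0 - rho * rho
        return M
    idx = np.arange(T)
    M[idx, idx] = 1.0 + rho * rho
    M[0, 0] = M[-1, -1] = 1.0
    M[idx[:-1], idx[:-1] + 1] = -rho
    M[idx[:-1] + 1, idx[:-1]] = -rho
    return M


def _run_chain(design: DesignMatrix, priors: PriorConfig, warmup: int, draws: int, rng):
    X, y = design.X, design.y
    n, p = X.shape
    K, T = design.K, design.T
    ncells = K * T
    d = p + ncells
    cell = design.cell_index

    Z = sp.csr_matrix((np.ones(n), (np.arange(n), cell)), shape=(n, ncells))
    Zt = Z.T.tocsr()
    kappa = y - 0.5
    b = np.empty(d)
    b[:p] = X.T @ kappa
    b[p:] = Zt @ kappa

    beta = np.zeros(p)
    u = np.zeros((K, T))
    rho, sigma = 0.0, 0.5

    out_beta = np.empty((draws, p))
    out_u = np.empty((draws, K, T))
    out_rho = np.empty(draws)
    out_sigma = np.empty(draws)

    prec = np.empty((d, d))
    beta_prec = 1.0 / priors.beta_sd ** 2

    for it in range(warmup + draws):
        eta = X @ beta + u.ravel()[cell]
        omega = pg_draw(eta, rng)

        wX = X * omega[:, None]
        prec[:p, :p] = X.T @ wX
        prec[:p, :p].flat[:: p + 1] += beta_prec
        XtOZ = (Zt @ wX).T  # (p, ncells)
        prec[:p, p:] = XtOZ
        prec[p:, :p] = XtOZ.T
        M = _ar1_precision(T, rho) / sigma ** 2
        prec[p:, p:] = np.kron(np.eye(K), M)
        prec[p:, p:].flat[:: ncells + 1] += Zt @ omega

        cf = sla.cho_factor(prec, lower=True, check_finite=False)
        mean = sla.cho_solve(cf, b, check_finite=False)
        z = rng.standard_normal(d)
        theta = mean + sla.solve_triangular(
            cf[0].T, z, lower=False, check_finite=False
        )
        beta = theta[:p]
        u = theta[p:].reshape(K, T)

        # sigma | u, rho  (slice on log sigma; HalfNormal prior + Jacobian)
        q = _ar1_quad(u, rho)
        ss2 = 2.0 * priors.sigma_scale ** 2

        def logf_lsig(ls):
            s = math.exp(ls)
            return -K * T * ls - q / (2.0 * s * s) - s * s / ss2 + ls

        lsig = _slice_sample(math.log(sigma), logf_lsig, rng, w=0.5)
        sigma = math.exp(lsig)

        # rho | u, sigma  (slice on (-1, 1); Uniform prior)
        s2 = sigma ** 2

        def logf_rho(r):
            if abs(r) >= 1.0:
                return -np.inf
            return 0.5 * K * math.log(1.0 - r * r) - _ar1_quad(u, r) / (2.0 * s2)

        rho = _slice_sample(rho, logf_rho, rng, w=0.3, lower=-0.999999, upper=0.999999)

        # Interweaving (ASIS) move for sigma: hold the standardized effects
        # u_tilde = u / sigma fixed and re-draw sigma against the likelihood.
        # In this non-centered parameterization u_tilde ~ AR(1) with unit
        # innovation sd, independent of sigma, so the conditional is
        # likelihood x HalfNormal prior. This breaks the strong coupling
        # between sigma and the magnitude of u that otherwise stalls mixing.
        u_tilde = (u / sigma).ravel()[cell]
        eta_base = X @ beta

        def logf_lsig_nc(ls):
            s = math.exp(ls)
            eta_nc = eta_base + s * u_tilde
            ll = float(np.sum(y * eta_nc - np.logaddexp(0.0, eta_nc)))
            return ll - s * s / ss2 + ls

        lsig = _slice_sample(math.log(sigma), logf_lsig_nc, rng, w=0.5)
        new_sigma = math.exp(lsig)
        u = u * (new_sigma / sigma)
        sigma = new_sigma

        if it >= warmup:
            j = it - warmup
            out_beta[j] = beta
            out_u[j] = u
            out_rho[j] = rho
            out_sigma[j] = sigma

    return out_beta, out_u, out_rho, out_sigma


def fit(
    records: pd.DataFrame,
    specs: Sequence[CovariateSpec],
    sampler: SamplerConfig | None = None,
    priors: PriorConfig | None = None,
    effect_level: str = "ea",
) -> PosteriorDraws:
    """Draw from the joint posterior of (beta, u, rho, sigma) by MCMC.

    The target density is exactly ``log_likelihood + log_prior``. Runs
    ``sampler.chains`` independent chains (seeded from ``sampler.seed``),
    discards ``warmup`` iterations each, and attaches convergence warnings
    when the rank-normalized split R-hat or effective sample size breaches
    the configured thresholds. The run is never discarded on warning.
    """
    sampler = sampler or SamplerConfig()
    priors = priors or PriorConfig()
    design = build_design(records, specs, effect_level=effect_level)
    if design.K < 2:
        raise ValueError("need at least 2 areas to fit the hierarchical model")
    y = design.y
    if y.min() == y.max():
        warnings.warn("degenerate outcome: all y identical; fit proceeds", UserWarning)

    seeds = np.random.SeedSequence(sampler.seed).spawn(sampler.chains)
    chains = [
        _run_chain(design, priors, sampler.warmup, sampler.draws, np.random.default_rng(s))
        for s in seeds
    ]
    post = PosteriorDraws(
        beta=np.stack([c[0] for c in chains]),
        u=np.stack([c[1] for c in chains]),
        rho=np.stack([c[2] for c in chains]),
        sigma=np.stack([c[3] for c in chains]),
        columns=design.columns,
        area_ids=design.area_ids,
        rounds=design.rounds,
        transforms=design.transforms,
        effect_level=design.effect_level,
        seed=sampler.seed,
        warmup=sampler.warmup,
    )
    if sampler.chains >= 2:
        _warn_convergence(post, sampler)
    return post


def _warn_convergence(post: PosteriorDraws, sampler: SamplerConfig) -> None:
    import arviz as az

    idata = post.to_arviz()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    worst_rhat = max(float(rhat[v].max()) for v in rhat.data_vars)
    worst_ess = min(float(ess[v].min()) for v in ess.data_vars)
    if worst_rhat > sampler.rhat_warn:
        warnings.warn(
            f"non-convergence: max R-hat {worst_rhat:.3f} > {sampler.rhat_warn}",
            UserWarning,
        )
    if worst_ess < sampler.ess_warn:
        warnings.warn(
            f"low effective sample size: min ESS {worst_ess:.0f} < {sampler.ess_warn:.0f}",
            UserWarning,
        )


def predict_p(
    draws: PosteriorDraws,
    design: DesignMatrix,
    zero_u: bool = False,
    rng: np.random.Generator | None = None,
    chunk: int | None = None,
) -> np.ndarray:
    """Per-draw probabilities P^(s) = expit(X beta^(s) + u^(s)_kt), shape (S, n).

    ``design`` must be built with the stored transforms and the fitted
    area/round sets (pass ``area_ids=draws.area_ids`` etc. to
    :func:`build_design`). With ``zero_u`` the random effects are zeroed,
    giving the covariate-only regression surface. Areas absent from the fit
    are flagged and their effects drawn from the stationary AR(1) prior per
    draw (``rng`` required).
    """
    if design.columns != draws.columns:
        raise ValueError("design columns do not match the fitted design")
    S = draws.S
    beta = draws.beta_flat

    known = set(draws.area_ids)
    new_areas = [a for a in design.area_ids if a not in known]
    if new_areas and not zero_u:
        warnings.warn(
            f"extrapolating to {len(new_areas)} area(s) absent from the fit; "
            "their effects are drawn from the AR(1) prior",
            UserWarning,
        )
        if rng is None:
            raise ValueError("rng required to extrapolate to unfitted areas")

    apos = {a: i for i, a in enumerate(draws.area_ids)}
    T = len(draws.rounds)
    eta_base = beta @ design.X.T  # (S, n)
    if zero_u:
        return expit(eta_base)

    u_full = np.empty((S, design.K, T))
    for j, a in enumerate(design.area_ids):
        if a in apos:
            u_full[:, j, :] = draws.u_flat[:, apos[a], :]
        else:
            sig = draws.sigma_flat
            rho = draws.rho_flat
            e = rng.standard_normal((S, T))
            path = np.empty((S, T))
            path[:, 0] = e[:, 0] * sig / np.sqrt(1.0 - rho ** 2)
            for t in range(1, T):
                path[:, t] = rho * path[:, t - 1] + sig * e[:, t]
            u_full[:, j, :] = path
    cell = design.area_index * T + design.round_index
    eta = eta_base + u_full.reshape(S, -1)[:, cell]
    return expit(eta)
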