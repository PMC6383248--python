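"""Model checking: shrinkage comparisons, posterior-predictive residuals,
convergence reporting.

Shrinkage tables quantify how far model estimates move from the unstable
direct estimates toward the covariate regression surface, and how much the
uncertainty interval narrows. The Z-value is the posterior-predictive
standardized residual of a unit-round's observed user count,

    Z = (O - E[O~]) / sd(O~),   O~ | draw s  ~  sum_i Bernoulli(P^(s)_i),

computed either from analytic binomial moments averaged over draws (with
the between-draw variance of the predictive mean added, law of total
variance) or by simulation. Values near 0 with unit spread indicate the
model predicts unit-level counts well; large |Z| flags extreme units.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from scipy.special import expit

from .model import DesignMatrix, PosteriorDraws, predict_p

logger = logging.getLogger(__name__)

__all__ = ["shrinkage_table", "z_values", "convergence_report"]


def _group_masks(records: pd.DataFrame, level: str, round: int | None = None):
    col = "ea_id" if level == "EA" else "region_id"
    rounds = sorted(records["round"].unique()) if round is None else [round]
    for unit in sorted(records[col].astype(str).unique()):
        for t in rounds:
            m = ((records[col].astype(str) == unit) & (records["round"] == t)).to_numpy()
            if m.any():
                yield unit, t, m


def shrinkage_table(
    direct: pd.DataFrame,
    draws: PosteriorDraws,
    design: DesignMatrix,
    level: str = "EA",
    ui_level: float = 0.95,
) -> pd.DataFrame:
    """One row per unit-round comparing direct, model, and regression-only
    estimates.

    ``direct`` is a direct-estimate table (columns unit_id, round, estimate,
    ui_lower, ui_upper, n) at the same level. Units present in only one
    source are logged and skipped. The regression-only prediction zeroes the
    random effects in every draw. Model aggregation is unweighted at EA
    level (matching the raw-ratio direct estimate) and weighted at region
    level.
    """
    records = design.records
    P = predict_p(draws, design)
    P0 = predict_p(draws, design, zero_u=True)
    use_weights = level != "EA"
    qs = [(1 - ui_level) / 2, 0.5, 1 - (1 - ui_level) / 2]

    dkey = {(str(r.unit_id), int(r.round)): r for r in direct.itertuples()}
    rows = []
    seen = set()
    for unit, t, m in _group_masks(records, level):
        seen.add((unit, t))
        if (unit, t) not in dkey:
            logger.info("unit %s round %s has no direct estimate; skipped", unit, t)
            continue
        d = dkey[(unit, t)]
        w = records.loc[m, "weight"].to_numpy(dtype=float) if use_weights else np.ones(m.sum())
        w = w / w.sum()
        bhm = P[:, m] @ w
        reg = P0[:, m] @ w
        b_lo, b_med, b_hi = np.quantile(bhm, qs)
        rows.append(
            {
                "unit_id": unit,
                "round": t,
                "n": int(d.n),
                "direct": float(d.estimate),
                "direct_lower": float(d.ui_lower),
                "direct_upper": float(d.ui_upper),
                "bhm": float(b_med),
                "bhm_lower": float(b_lo),
                "bhm_upper": float(b_hi),
                "regression": float(np.median(reg)),
                "abs_shrinkage": abs(float(b_med) - float(d.estimate)),
                "width_ratio": float(
                    (b_hi - b_lo) / max(d.ui_upper - d.ui_lower, 1e-12)
                ),
            }
        )
    for key in set(dkey) - seen:
        logger.info("direct estimate for %s has no model rows; skipped", key)
    return pd.DataFrame(rows)


def z_values(
    draws: PosteriorDraws,
    design: DesignMatrix,
    level: str = "EA",
    round: int | None = None,
    method: str = "analytic",
    rng: np.random.Generator | None = None,
    marginalize_u: bool = True,
) -> pd.DataFrame:
    """Posterior-predictive standardized residuals of unit-round user counts.

    With ``method="analytic"`` the predictive moments are
    mean = E_s[sum_i P_i^(s)] and var = E_s[sum_i P_i^(s)(1-P_i^(s))] +
    Var_s[sum_i P_i^(s)]. With ``method="simulate"`` counts are drawn per
    posterior draw; both routes agree up to Monte-Carlo error.

    By default (``marginalize_u=True``, requires ``rng``) each unit's random
    effect is integrated over its stationary AR(1) prior, redrawn per posterior
    draw of (rho, sigma). This is the calibrated diagnostic: under a correctly
    specified model the Z-values are approximately standard normal across
    units. Conditioning on the unit's own fitted effect
    (``marginalize_u=False``) recenters the predictive on the unit's own data,
    deflating the residuals and the diagnostic's power to flag outliers.
    """
    records = design.records
    y = design.y
    if marginalize_u:
        if rng is None:
            raise ValueError("marginalize_u=True needs an rng to draw prior effects")
        S = draws.S
        T = len(draws.rounds)
        sig = draws.sigma_flat
        rho = draws.rho_flat
        e = rng.standard_normal((S, design.K, T))
        path = np.empty((S, design.K, T))
        path[:, :, 0] = e[:, :, 0] * (sig / np.sqrt(1.0 - rho ** 2))[:, None]
        for t in range(1, T):
            path[:, :, t] = rho[:, None] * path[:, :, t - 1] + sig[:, None] * e[:, :, t]
        eta = draws.beta_flat @ design.X.T + path.reshape(S, -1)[:, design.cell_index]
        P = expit(eta)
    else:
        P = predict_p(draws, design)
    rows = []
    for unit, t, m in _group_masks(records, level, round):
        n = int(m.sum())
        observed = float(y[m].sum())
        Pm = P[:, m]
        per_draw_mean = Pm.sum(axis=1)
        if method == "analytic":
            mean = float(per_draw_mean.mean())
            var = float((Pm * (1.0 - Pm)).sum(axis=1).mean() + per_draw_mean.var(ddof=1))
        elif method == "simulate":
            if rng is None:
                raise ValueError("simulation route needs an rng")
            counts = rng.binomial(1, Pm).sum(axis=1)
            mean = float(counts.mean())
            var = float(counts.var(ddof=1))
        else:
            raise ValueError("method must be 'analytic' or 'simulate'")
        if var <= 0.0:
            logger.info("unit %s round %s has degenerate predictive variance; skipped", unit, t)
            continue
        rows.append(
            {
                "unit_id": unit,
                "round": t,
                "n": n,
                "observed": observed,
                "pred_mean": mean,
                "pred_sd": float(np.sqrt(var)),
                "z": (observed - mean) / float(np.sqrt(var)),
            }
        )
    return pd.DataFrame(rows)


def convergence_report(
    draws: PosteriorDraws, rhat_warn: float = 1.05, rhat_fail: float = 1.1, ess_min: float = 100.0
) -> pd.DataFrame:
    """Per-parameter rank-normalized split R-hat and bulk effective sample
    size, with pass/warn/fail status. Single-chain runs still produce the
    split diagnostic but are flagged."""
    import warnings

    import arviz as az

    idata = draws.to_arviz()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    rows = []
    for var in ("beta", "u", "rho", "sigma"):
        r = np.atleast_1d(np.asarray(rhat[var]).ravel())
        e = np.atleast_1d(np.asarray(ess[var]).ravel())
        if var == "beta":
            names = [f"beta[{c}]" for c in draws.columns]
        elif var == "u":
            names = [f"u[{a},{t}]" for a in draws.area_ids for t in draws.rounds]
        else:
            names = [var]
        for name, ri, ei in zip(names, r, e):
            status = "pass"
            if ri > rhat_fail:
                status = "fail"
            elif ri > rhat_warn or ei < ess_min:
                status = "warn"
            rows.append({"parameter": name, "rhat": float(ri), "ess": float(ei), "status": status})
    out = pd.DataFrame(rows)
    out.attrs["single_chain"] = draws.n_chains < 2
    out.attrs["overall"] = (
        "fail" if (out["status"] == "fail").any() else ("warn" if (out["status"] == "warn").any() else "pass")
    )
    return out
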