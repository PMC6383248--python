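"""Posterior aggregation: regional/national prevalence, change, targets.

Every woman's per-draw probability P^(s)_ikt is averaged (with survey
weights) within the requested level-round, one number per posterior draw.
All downstream summaries — point estimate (posterior median), equal-tailed
95% uncertainty interval, round-to-round change, probability of exceeding a
target — are computed on those draw vectors, so serial correlation between
rounds is carried through automatically: the change draws are differences
within a joint posterior draw, never differences of summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import DesignMatrix, PosteriorDraws

__all__ = [
    "RegionalPosterior",
    "ChangePosterior",
    "aggregate_mcpr",
    "change_posterior",
    "prob_target",
    "mcpr_table",
    "change_table",
]


class EmptyCellError(ValueError):
    """No records at the requested level-round."""


class AlignmentError(ValueError):
    """Draw vectors from different fits or of different lengths."""


@dataclass
class RegionalPosterior:
    region_id: str  # "ALL" for national
    round: int
    draws: np.ndarray  # (S,) per-draw mCPR
    ui_level: float = 0.95

    @property
    def point(self) -> float:
        return float(np.median(self.draws))

    @property
    def ui_lower(self) -> float:
        return float(np.quantile(self.draws, (1.0 - self.ui_level) / 2.0))

    @property
    def ui_upper(self) -> float:
        return float(np.quantile(self.draws, 1.0 - (1.0 - self.ui_level) / 2.0))

    @property
    def ui_width(self) -> float:
        return self.ui_upper - self.ui_lower


@dataclass
class ChangePosterior:
    region_id: str
    round_pair: tuple[int, int]
    draws: np.ndarray  # per-draw difference, t1 minus t0 within draw
    ui_level: float = 0.95

    @property
    def median_change(self) -> float:
        return float(np.median(self.draws))

    @property
    def ui_lower(self) -> float:
        return float(np.quantile(self.draws, (1.0 - self.ui_level) / 2.0))

    @property
    def ui_upper(self) -> float:
        return float(np.quantile(self.draws, 1.0 - (1.0 - self.ui_level) / 2.0))

    @property
    def excludes_zero(self) -> bool:
        return self.ui_lower > 0.0 or self.ui_upper < 0.0


def aggregate_mcpr(
    P: np.ndarray,
    records: pd.DataFrame,
    level: str,
    round: int,
    unit: str | None = None,
    use_weights: bool = True,
    ui_level: float = 0.95,
) -> RegionalPosterior:
    """Weighted mean of per-draw probabilities over one level-round.

    ``P`` is an (S, n) matrix aligned row-for-row with ``records``.
    ``level`` is "region" (requires ``unit``), "national", or "EA"
    (requires ``unit``; used by the shrinkage diagnostics).
    """
    if P.shape[1] != len(records):
        raise AlignmentError(f"P has {P.shape[1]} columns for {len(records)} records")
    mask = (records["round"] == round).to_numpy()
    if level == "national":
        uid = "ALL"
    elif level == "region":
        if unit is None:
            raise ValueError("region-level aggregation needs a unit label")
        mask &= (records["region_id"] == unit).to_numpy()
        uid = unit
    elif level == "EA":
        if unit is None:
            raise ValueError("EA-level aggregation needs a unit label")
        mask &= (records["ea_id"] == unit).to_numpy()
        uid = unit
    else:
        raise ValueError("level must be 'region', 'national' or 'EA'")
    if not mask.any():
        raise EmptyCellError(f"no records for {level} {uid!r} in round {round}")
    w = records.loc[mask, "weight"].to_numpy(dtype=float) if use_weights else np.ones(mask.sum())
    w = w / w.sum()
    draws = P[:, mask] @ w
    return RegionalPosterior(region_id=uid, round=int(round), draws=draws, ui_level=ui_level)


def change_posterior(post_t0: RegionalPosterior, post_t1: RegionalPosterior) -> ChangePosterior:
    """Draw-wise difference t1 - t0 for the same unit within one joint fit."""
    if post_t0.region_id != post_t1.region_id:
        raise AlignmentError(
            f"units differ: {post_t0.region_id!r} vs {post_t1.region_id!r}"
        )
    if post_t0.draws.shape != post_t1.draws.shape:
        raise AlignmentError("draw vectors have different lengths; not draw-aligned")
    return ChangePosterior(
        region_id=post_t0.region_id,
        round_pair=(post_t0.round, post_t1.round),
        draws=post_t1.draws - post_t0.draws,
        ui_level=post_t0.ui_level,
    )


def prob_target(post: RegionalPosterior | ChangePosterior, target: float) -> float:
    """Posterior probability that the quantity strictly exceeds ``target``."""
    return float(np.mean(post.draws > target))


def _unit_round_draws(
    draws: PosteriorDraws,
    design: DesignMatrix,
    use_weights: bool,
    group_col: str,
    chunk: int = 200,
) -> dict[tuple[str, int], np.ndarray]:
    """Per-draw weighted mCPR for every (unit, round), computed in draw
    chunks so the full (S, n) probability matrix is never materialized."""
    records = design.records
    S = draws.S
    rounds = sorted(records["round"].unique())
    units = sorted(records[group_col].astype(str).unique()) + ["ALL"]
    masks, weights = {}, {}
    for unit in units:
        for t in rounds:
            m = (records["round"] == t).to_numpy()
            if unit != "ALL":
                m &= (records[group_col].astype(str) == unit).to_numpy()
            if not m.any():
                continue
            w = records.loc[m, "weight"].to_numpy(dtype=float) if use_weights else np.ones(m.sum())
            masks[(unit, t)] = m
            weights[(unit, t)] = w / w.sum()
    out = {key: np.empty(S) for key in masks}
    beta = draws.beta_flat
    u = draws.u_flat.reshape(S, -1)
    cell = design.cell_index
    from scipy.special import expit

    for lo in range(0, S, chunk):
        hi = min(lo + chunk, S)
        P = expit(beta[lo:hi] @ design.X.T + u[lo:hi][:, cell])
        for key, m in masks.items():
            out[key][lo:hi] = P[:, m] @ weights[key]
    return out


def mcpr_table(
    draws: PosteriorDraws,
    design: DesignMatrix,
    use_weights: bool = True,
    ui_level: float = 0.95,
) -> pd.DataFrame:
    """Region x round posterior summary table (with the national "ALL" row):
    columns region_id, round, mcpr, ui_lower, ui_upper."""
    agg = _unit_round_draws(draws, design, use_weights, "region_id")
    rows = []
    for (unit, t), d in sorted(agg.items()):
        rp = RegionalPosterior(unit, t, d, ui_level)
        rows.append(
            {
                "region_id": unit,
                "round": t,
                "mcpr": rp.point,
                "ui_lower": rp.ui_lower,
                "ui_upper": rp.ui_upper,
            }
        )
    return pd.DataFrame(rows).sort_values(["region_id", "round"]).reset_index(drop=True)


def change_table(
    draws: PosteriorDraws,
    design: DesignMatrix,
    t0: int | None = None,
    t1: int | None = None,
    use_weights: bool = True,
    ui_level: float = 0.95,
) -> pd.DataFrame:
    """Region-level posterior change summaries between two rounds (defaults:
    first and last observed round): change, ui_lower, ui_upper,
    excludes_zero."""
    records = design.records
    rounds = sorted(records["round"].unique())
    t0 = rounds[0] if t0 is None else t0
    t1 = rounds[-1] if t1 is None else t1
    agg = _unit_round_draws(draws, design, use_weights, "region_id")
    rows = []
    units = sorted({u for (u, _) in agg})
    for unit in units:
        if (unit, t0) not in agg or (unit, t1) not in agg:
            continue
        cp = ChangePosterior(unit, (t0, t1), agg[(unit, t1)] - agg[(unit, t0)], ui_level)
        rows.append(
            {
                "region_id": unit,
                "round_from": t0,
                "round_to": t1,
                "change": cp.median_change,
                "ui_lower": cp.ui_lower,
                "ui_upper": cp.ui_upper,
                "excludes_zero": cp.excludes_zero,
            }
        )
    return pd.DataFrame(rows)
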