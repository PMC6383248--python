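"""Design-based direct estimates of prevalence.

The EA-level direct estimate is the raw ratio (users / sample size) with a
Wilson score interval. Region and national estimates are survey-weighted
proportions with an EA-clustered Taylor-linearization variance and a Wald
interval on the logit scale, back-transformed so the interval respects
[0, 1]. These are the comparators the hierarchical model is judged against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = ["DirectEstimate", "ea_direct", "region_direct", "national_direct", "direct_table"]


class EmptyCellError(ValueError):
    """No records for the requested unit-round."""


@dataclass
class DirectEstimate:
    level: str  # "EA", "region" or "national"
    unit_id: str
    round: int
    estimate: float
    n: int
    ui_lower: float
    ui_upper: float
    ui_level: float = 0.95
    clustered: bool = True  # False when variance could not use >= 2 EA clusters

    def __post_init__(self) -> None:
        if not (0.0 <= self.ui_lower <= self.estimate <= self.ui_upper <= 1.0):
            raise ValueError(
                f"interval ordering violated: {self.ui_lower}, {self.estimate}, {self.ui_upper}"
            )
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @property
    def ui_width(self) -> float:
        return self.ui_upper - self.ui_lower


def ea_direct(records: pd.DataFrame, ea: str, round: int, ui_level: float = 0.95) -> DirectEstimate:
    """Unweighted users/sample-size ratio for one EA-round, Wilson interval."""
    sub = records[(records["ea_id"] == ea) & (records["round"] == round)]
    if len(sub) == 0:
        raise EmptyCellError(f"no records for EA {ea!r} in round {round}")
    n = len(sub)
    users = int(sub["y"].sum())
    lo, hi = proportion_confint(users, n, alpha=1.0 - ui_level, method="wilson")
    p = users / n
    return DirectEstimate(
        level="EA",
        unit_id=ea,
        round=int(round),
        estimate=p,
        n=n,
        # clip against the point estimate too: at the 0- and n-user boundaries
        # the Wilson bound can land on the wrong side of p by float roundoff
        ui_lower=min(float(np.clip(lo, 0.0, 1.0)), p),
        ui_upper=max(float(np.clip(hi, 0.0, 1.0)), p),
        ui_level=ui_level,
    )


def _weighted_clustered(
    y: np.ndarray, w: np.ndarray, cluster: np.ndarray
) -> tuple[float, float, bool]:
    """Weighted proportion and its EA-clustered linearization variance.

    p_hat = sum(w y) / sum(w); with cluster score totals
    z_c = sum_{i in c} w_i (y_i - p_hat), Var(p_hat) ~=
    m/(m-1) * sum_c z_c^2 / (sum w)^2 for m clusters. Falls back to the
    woman-level (unclustered) variance when only one cluster is present.
    """
    wsum = w.sum()
    p = float(np.sum(w * y) / wsum)
    resid = w * (y - p)
    labels, inv = np.unique(cluster, return_inverse=True)
    m = len(labels)
    if m >= 2:
        z = np.bincount(inv, weights=resid)
        var = m / (m - 1) * float(np.sum(z ** 2)) / wsum ** 2
        return p, var, True
    n = len(y)
    var = (n / max(n - 1, 1)) * float(np.sum(resid ** 2)) / wsum ** 2
    return p, var, False


def _logit_wald(p: float, var: float, n: int, ui_level: float) -> tuple[float, float]:
    from scipy.stats import norm

    z = norm.ppf(0.5 + ui_level / 2.0)
    if p <= 0.0 or p >= 1.0 or var <= 0.0:
        # boundary: fall back to Wilson on the effective count
        lo, hi = proportion_confint(round(p * n), n, alpha=1.0 - ui_level, method="wilson")
        return float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))
    lp = np.log(p / (1.0 - p))
    se_lp = np.sqrt(var) / (p * (1.0 - p))
    lo = 1.0 / (1.0 + np.exp(-(lp - z * se_lp)))
    hi = 1.0 / (1.0 + np.exp(-(lp + z * se_lp)))
    return float(lo), float(hi)


def region_direct(
    records: pd.DataFrame,
    region: str,
    round: int,
    use_weights: bool = True,
    ui_level: float = 0.95,
) -> DirectEstimate:
    """Survey-weighted regional proportion with EA-clustered uncertainty."""
    sub = records[(records["region_id"] == region) & (records["round"] == round)]
    if len(sub) == 0:
        raise EmptyCellError(f"no records for region {region!r} in round {round}")
    y = sub["y"].to_numpy(dtype=float)
    w = sub["weight"].to_numpy(dtype=float) if use_weights else np.ones(len(sub))
    p, var, clustered = _weighted_clustered(y, w, sub["ea_id"].to_numpy())
    lo, hi = _logit_wald(p, var, len(sub), ui_level)
    return DirectEstimate(
        level="region",
        unit_id=region,
        round=int(round),
        estimate=p,
        n=len(sub),
        ui_lower=min(lo, p),
        ui_upper=max(hi, p),
        ui_level=ui_level,
        clustered=clustered,
    )


def national_direct(
    records: pd.DataFrame, round: int, use_weights: bool = True, ui_level: float = 0.95
) -> DirectEstimate:
    sub = records[records["round"] == round]
    if len(sub) == 0:
        raise EmptyCellError(f"no records in round {round}")
    y = sub["y"].to_numpy(dtype=float)
    w = sub["weight"].to_numpy(dtype=float) if use_weights else np.ones(len(sub))
    p, var, clustered = _weighted_clustered(y, w, sub["ea_id"].to_numpy())
    lo, hi = _logit_wald(p, var, len(sub), ui_level)
    est = DirectEstimate(
        level="national",
        unit_id="ALL",
        round=int(round),
        estimate=p,
        n=len(sub),
        ui_lower=min(lo, p),
        ui_upper=max(hi, p),
        ui_level=ui_level,
        clustered=clustered,
    )
    return est


def direct_table(
    records: pd.DataFrame, level: str = "region", use_weights: bool = True
) -> pd.DataFrame:
    """All unit-round direct estimates at one level, in the shared CSV layout
    (level, unit_id, round, estimate, ui_lower, ui_upper, n)."""
    rounds = sorted(records["round"].unique())
    out = []
    if level == "EA":
        units = sorted(records["ea_id"].unique())
        for ea in units:
            for t in rounds:
                try:
                    out.append(ea_direct(records, ea, t))
                except EmptyCellError:
                    continue
    elif level == "region":
        units = sorted(records["region_id"].unique())
        for rg in units:
            for t in rounds:
                try:
                    out.append(region_direct(records, rg, t, use_weights=use_weights))
                except EmptyCellError:
                    continue
        for t in rounds:
            out.append(national_direct(records, t, use_weights=use_weights))
    else:
        raise ValueError("level must be 'EA' or 'region'")
    return pd.DataFrame(
        {
            "level": [e.level for e in out],
            "unit_id": [e.unit_id for e in out],
            "round": [e.round for e in out],
            "estimate": [e.estimate for e in out],
            "ui_lower": [e.ui_lower for e in out],
            "ui_upper": [e.ui_upper for e in out],
            "n": [e.n for e in out],
        }
    )
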