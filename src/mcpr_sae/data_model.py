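"""Tabular contract for woman-level survey records.

A dataset is a pandas DataFrame with one row per woman-interview and columns

    country_id, region_id, ea_id, woman_id, round, y, weight, <covariate...>

where ``y`` is the binary modern-contraceptive-use outcome, ``weight`` a
positive sampling weight, ``round`` the survey wave (1..T), and enumeration
areas (EAs) nest inside first-level administrative regions. Covariates are
declared through :class:`CovariateSpec`; the default specification carries
the twelve woman-level determinants of modern contraceptive use commonly
collected by family-planning surveys (residence, schooling, wealth quintile,
child survival, age, cohabitation, recent sexual activity, health-worker
visit, exposure to family-planning messaging, fertility intention, parity,
distance to the nearest facility).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

ID_COLUMNS = ["country_id", "region_id", "ea_id", "woman_id", "round", "y", "weight"]


class SchemaError(ValueError):
    """A required column is missing or mis-typed."""


class NestingError(ValueError):
    """An enumeration area appears under more than one region."""


class RecordValueError(ValueError):
    """A row violates a field invariant (y not in {0,1}, weight <= 0, ...)."""


class EmptyInputError(ValueError):
    """An operation received an empty table."""


class AllEAsUnbalancedError(ValueError):
    """No enumeration area is observed in every round."""


@dataclass(frozen=True)
class CovariateSpec:
    """Declared type and encoding of one model covariate.

    kind is one of ``binary``, ``categorical``, ``continuous``. Categorical
    covariates carry ordered ``levels`` and a ``reference_level`` that is
    absorbed by the intercepts; continuous covariates may request
    standardization (center/scale using the estimation rows).
    """

    name: str
    kind: str
    levels: tuple[str, ...] = ()
    reference_level: str | None = None
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "categorical", "continuous"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "categorical":
            if len(self.levels) < 2:
                raise ValueError(f"categorical covariate {self.name!r} needs >= 2 levels")
            ref = self.reference_level if self.reference_level is not None else self.levels[0]
            if ref not in self.levels:
                raise ValueError(
                    f"reference level {ref!r} not among levels of {self.name!r}"
                )
            object.__setattr__(self, "reference_level", ref)

    @property
    def design_width(self) -> int:
        if self.kind == "categorical":
            return len(self.levels) - 1
        return 1


def default_covariate_spec() -> list[CovariateSpec]:
    """The twelve-covariate default specification.

    Codings are plausible survey encodings and fully user-overridable:
    binary indicators for yes/no items, five wealth quintiles, three
    schooling levels, continuous (standardized) age and facility distance,
    and continuous parity.
    """
    return [
        CovariateSpec("residence", "binary"),  # 1 = urban
        CovariateSpec("schooling", "categorical", ("none", "primary", "secondary_plus"), "none"),
        CovariateSpec("wealth_quintile", "categorical", ("q1", "q2", "q3", "q4", "q5"), "q1"),
        CovariateSpec("child_survival", "binary"),  # 1 = has experienced a child death
        CovariateSpec("age", "continuous", standardize=True),
        CovariateSpec("cohabitation", "binary"),  # 1 = married / living with partner
        CovariateSpec("recent_sex", "binary"),
        CovariateSpec("health_worker_visit", "binary"),
        CovariateSpec("fp_message", "binary"),  # exposure to family-planning messaging
        CovariateSpec("fertility_intention", "binary"),  # 1 = wants another child soon
        CovariateSpec("parity", "continuous", standardize=False),
        CovariateSpec("distance_facility", "continuous", standardize=True),
    ]


def covariate_spec_from_dict(items: Sequence[dict]) -> list[CovariateSpec]:
    specs = []
    for d in items:
        specs.append(
            CovariateSpec(
                name=d["name"],
                kind=d["kind"],
                levels=tuple(d.get("levels", ()) or ()),
                reference_level=d.get("reference_level"),
                standardize=bool(d.get("standardize", False)),
            )
        )
    return specs


def load_covariate_spec(path) -> list[CovariateSpec]:
    """Read a covariate specification from a YAML (or JSON) file."""
    with open(path) as fh:
        items = yaml.safe_load(fh)
    return covariate_spec_from_dict(items)


def save_covariate_spec(specs: Sequence[CovariateSpec], path) -> None:
    items = [
        {
            "name": s.name,
            "kind": s.kind,
            "levels": list(s.levels),
            "reference_level": s.reference_level,
            "standardize": s.standardize,
        }
        for s in specs
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(items, fh, sort_keys=False)


def validate_records(df: pd.DataFrame, specs: Sequence[CovariateSpec] | None = None) -> pd.DataFrame:
    """Validate a record table in place and return it.

    Raises :class:`SchemaError`, :class:`RecordValueError` or
    :class:`NestingError` with row-level context on the first violation.
    """
    required = list(ID_COLUMNS)
    if specs is not None:
        required += [s.name for s in specs]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    y = pd.to_numeric(df["y"], errors="coerce")
    bad = df.index[~y.isin([0, 1])]
    if len(bad):
        raise RecordValueError(f"y must be 0 or 1; offending row index(es): {list(bad[:5])}")
    w = pd.to_numeric(df["weight"], errors="coerce")
    bad = df.index[~(w > 0)]
    if len(bad):
        raise RecordValueError(f"weight must be > 0; offending row index(es): {list(bad[:5])}")
    rnd = pd.to_numeric(df["round"], errors="coerce")
    bad = df.index[~((rnd >= 1) & (rnd == rnd.round()))]
    if len(bad):
        raise RecordValueError(f"round must be a positive integer; offending row index(es): {list(bad[:5])}")

    nest = df.groupby("ea_id")["region_id"].nunique()
    multi = nest[nest > 1]
    if len(multi):
        raise NestingError(
            f"EA(s) mapped to more than one region: {list(multi.index[:5])}"
        )

    df = df.copy()
    df["y"] = y.astype(np.int64)
    df["round"] = rnd.astype(np.int64)
    df["weight"] = w.astype(np.float64)
    return df


def read_dataset(path, specs: Sequence[CovariateSpec] | None = None) -> pd.DataFrame:
    """Read and validate a woman-level CSV (UTF-8, header row, '' = missing)."""
    df = pd.read_csv(
        path,
        dtype={"country_id": str, "region_id": str, "ea_id": str, "woman_id": str},
        keep_default_na=True,
        na_values=[""],
    )
    return validate_records(df, specs)


def write_dataset(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


@dataclass
class DatasetProfile:
    """Per-round survey profile: distinct regions, EAs and women, plus the
    per-EA-round cell sizes n_kt and the EAs missing from some round."""

    per_round: pd.DataFrame  # index round; columns n_regions, n_eas, n_women
    n_kt: pd.DataFrame  # index ea_id; columns rounds; values cell sizes
    eas_not_all_rounds: list[str] = field(default_factory=list)

    @property
    def n_rounds(self) -> int:
        return len(self.per_round)

    @property
    def totals(self) -> dict:
        return {
            "n_regions": int(self.per_round["n_regions"].max()),
            "n_eas": int(self.n_kt.shape[0]),
            "n_women": int(self.per_round["n_women"].sum()),
            "n_rounds": int(self.n_rounds),
        }


def profile_dataset(df: pd.DataFrame) -> DatasetProfile:
    """Summarize a record table round by round (survey-description style)."""
    if len(df) == 0:
        raise EmptyInputError("cannot profile an empty table")
    per_round = (
        df.groupby("round")
        .agg(
            n_regions=("region_id", "nunique"),
            n_eas=("ea_id", "nunique"),
            n_women=("woman_id", "size"),
        )
        .sort_index()
    )
    n_kt = df.pivot_table(index="ea_id", columns="round", values="y", aggfunc="size").fillna(0).astype(int)
    all_rounds = per_round.index
    incomplete = sorted(n_kt.index[(n_kt[all_rounds] == 0).any(axis=1)])
    return DatasetProfile(per_round=per_round, n_kt=n_kt, eas_not_all_rounds=list(incomplete))


def filter_balanced_eas(df: pd.DataFrame) -> pd.DataFrame:
    """Keep only EAs observed in every round of the dataset (idempotent)."""
    if len(df) == 0:
        raise EmptyInputError("cannot filter an empty table")
    prof = profile_dataset(df)
    keep = set(prof.n_kt.index) - set(prof.eas_not_all_rounds)
    if not keep:
        raise AllEAsUnbalancedError("no enumeration area is present in all rounds")
    return df[df["ea_id"].isin(keep)].reset_index(drop=True)
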