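"""Shared data model: cohorts, per-variable metadata, and disk round-trip.

A :class:`Cohort` is the universal currency of the pipeline: a rectangular
table of records together with one :class:`VariableMeta` per column.  Every
column is either categorical or continuous and plays one of three roles —
``core_predictor``, ``outcome`` (exactly one, binary categorical) or
``adjunct``.  Quasi-identifier and parameter-of-interest flags ride on the
metadata so that downstream stages (membership attack, replicability) need
no extra configuration.

On disk a cohort is a CSV (RFC-4180, header row, UTF-8, empty field =
missing) plus a JSON metadata sidecar.  In memory the single missing-value
sentinel is NaN for both types; categorical columns hold strings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._seeding import child_seed

__all__ = [
    "VariableMeta",
    "Cohort",
    "TrainHoldoutSplit",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "split_train_holdout",
    "METRIC_TABLE_COLUMNS",
]

#: Column order of the long-format metric table shared across the pipeline.
METRIC_TABLE_COLUMNS = [
    "dataset_id",
    "generator_id",
    "k_adjunct",
    "variant_id",
    "metric_name",
    "replicate",
    "value",
]

VTYPES = ("categorical", "continuous")
ROLES = ("core_predictor", "outcome", "adjunct")


class CohortValidationError(ValueError):
    """Raised when a cohort or its metadata violates an invariant."""


@dataclass
class VariableMeta:
    """Metadata for one column of a cohort."""

    name: str
    vtype: str  # "categorical" | "continuous"
    role: str  # "core_predictor" | "outcome" | "adjunct"
    categories: list[str] | None = None
    is_qi: bool = False
    is_parameter_of_interest: bool = False

    def __post_init__(self) -> None:
        if self.vtype not in VTYPES:
            raise CohortValidationError(f"unknown vtype {self.vtype!r} for {self.name!r}")
        if self.role not in ROLES:
            raise CohortValidationError(f"unknown role {self.role!r} for {self.name!r}")
        if self.vtype == "categorical" and self.categories is not None:
            self.categories = [str(c) for c in self.categories]


@dataclass
class Cohort:
    """A table of records plus per-variable metadata.

    ``records`` is a pandas DataFrame whose columns match ``meta`` exactly
    (same names, same order).  Missing values are NaN in both categorical
    (object dtype) and continuous (float dtype) columns.
    """

    records: pd.DataFrame
    meta: list[VariableMeta]
    dataset_id: str = "cohort"

    # -- metadata accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.records)

    def meta_for(self, name: str) -> VariableMeta:
        for m in self.meta:
            if m.name == name:
                return m
        raise KeyError(name)

    @property
    def outcome_name(self) -> str:
        return next(m.name for m in self.meta if m.role == "outcome")

    @property
    def core_predictor_names(self) -> list[str]:
        return [m.name for m in self.meta if m.role == "core_predictor"]

    @property
    def core_names(self) -> list[str]:
        """Core predictors plus the outcome."""
        return [m.name for m in self.meta if m.role in ("core_predictor", "outcome")]

    @property
    def adjunct_names(self) -> list[str]:
        return [m.name for m in self.meta if m.role == "adjunct"]

    @property
    def qi_names(self) -> list[str]:
        return [m.name for m in self.meta if m.is_qi]

    @property
    def parameter_of_interest(self) -> str | None:
        for m in self.meta:
            if m.is_parameter_of_interest:
                return m.name
        return None

    # -- operations ---------------------------------------------------------
    def project(self, columns: Sequence[str]) -> "Cohort":
        """Restrict to ``columns`` (order preserved from the cohort)."""
        missing = [c for c in columns if c not in self.records.columns]
        if missing:
            raise KeyError(f"unknown column(s): {missing}")
        keep = [m.name for m in self.meta if m.name in set(columns)]
        return Cohort(
            records=self.records[keep].copy(),
            meta=[m for m in self.meta if m.name in set(columns)],
            dataset_id=self.dataset_id,
        )

    def validate(self) -> "Cohort":
        names = [m.name for m in self.meta]
        if len(set(names)) != len(names):
            raise CohortValidationError("duplicate variable names in metadata")
        if list(self.records.columns) != names:
            raise CohortValidationError(
                "metadata does not match table columns: "
                f"{names} vs {list(self.records.columns)}"
            )
        if self.n < 1:
            raise CohortValidationError("cohort must contain at least one record")
        outcomes = [m for m in self.meta if m.role == "outcome"]
        if len(outcomes) != 1:
            raise CohortValidationError(
                f"exactly one outcome variable required, found {len(outcomes)}"
            )
        out = outcomes[0]
        if out.vtype != "categorical":
            raise CohortValidationError("outcome must be categorical")
        observed = self.records[out.name].dropna().unique()
        levels = set(out.categories) if out.categories else set(map(str, observed))
        if len(levels) != 2:
            raise CohortValidationError(
                f"outcome must be binary, has categories {sorted(levels)}"
            )
        pois = [m for m in self.meta if m.is_parameter_of_interest]
        if len(pois) > 1:
            raise CohortValidationError("at most one parameter-of-interest variable")
        if pois and pois[0].role != "core_predictor":
            raise CohortValidationError("parameter of interest must be a core predictor")
        for m in self.meta:
            if m.vtype == "categorical" and m.categories is not None:
                observed = set(self.records[m.name].dropna().astype(str).unique())
                extra = observed - set(m.categories)
                if extra:
                    raise CohortValidationError(
                        f"column {m.name!r} contains undeclared categories {sorted(extra)}"
                    )
        return self


@dataclass
class TrainHoldoutSplit:
    """Disjoint record-index sets for SDG training and the real holdout."""

    train_ids: np.ndarray
    holdout_ids: np.ndarray

    def __post_init__(self) -> None:
        self.train_ids = np.asarray(self.train_ids, dtype=np.int64)
        self.holdout_ids = np.asarray(self.holdout_ids, dtype=np.int64)
        if np.intersect1d(self.train_ids, self.holdout_ids).size:
            raise CohortValidationError("train and holdout index sets overlap")


# ---------------------------------------------------------------------------
# Disk round-trip


def _meta_to_json(meta: Iterable[VariableMeta]) -> list[dict]:
    out = []
    for m in meta:
        d = asdict(m)
        if d["categories"] is None:
            d.pop("categories")
        out.append(d)
    return out


def write_cohort(cohort: Cohort, table_path: str | Path, metadata_path: str | Path) -> None:
    """Write a cohort as CSV + JSON metadata sidecar (lossless round-trip)."""
    cohort.validate()
    table_path, metadata_path = Path(table_path), Path(metadata_path)
    df = cohort.records.copy()
    for m in cohort.meta:
        if m.vtype == "categorical":
            df[m.name] = df[m.name].astype(object).where(df[m.name].notna(), np.nan)
    df.to_csv(table_path, index=False, na_rep="")
    payload = {"dataset_id": cohort.dataset_id, "variables": _meta_to_json(cohort.meta)}
    metadata_path.write_text(json.dumps(payload, indent=2))


def read_cohort(table_path: str | Path, metadata_path: str | Path) -> Cohort:
    """Read a CSV + JSON metadata pair and validate all invariants."""
    payload = json.loads(Path(metadata_path).read_text())
    meta = [VariableMeta(**v) for v in payload["variables"]]
    names = [m.name for m in meta]
    df = pd.read_csv(
        table_path,
        dtype=str,
        keep_default_na=False,
        na_values=[""],
        skip_blank_lines=False,
    )
    if sorted(df.columns) != sorted(names):
        raise CohortValidationError(
            f"CSV columns {sorted(df.columns)} do not match metadata {sorted(names)}"
        )
    df = df[names]
    for m in meta:
        if m.vtype == "continuous":
            df[m.name] = pd.to_numeric(df[m.name], errors="raise")
        else:
            df[m.name] = df[m.name].astype(object)
    cohort = Cohort(records=df, meta=meta, dataset_id=payload.get("dataset_id", "cohort"))
    return cohort.validate()


# ---------------------------------------------------------------------------
# Train/holdout split


def split_train_holdout(
    cohort: Cohort, n_train: int, n_holdout: int, seed: int
) -> TrainHoldoutSplit:
    """Draw disjoint train/holdout index sets of exact sizes.

    The split is a deterministic function of ``(dataset_id, seed)`` only, so
    every variant of one dataset shares a single split: varying the variable
    set never changes which records the generator is trained on.
    """
    if n_train + n_holdout > cohort.n:
        raise CohortValidationError(
            f"n_train + n_holdout = {n_train + n_holdout} exceeds population size {cohort.n}"
        )
    rng = np.random.default_rng(child_seed(seed, "split", cohort.dataset_id))
    perm = rng.permutation(cohort.n)
    return TrainHoldoutSplit(
        train_ids=np.sort(perm[:n_train]),
        holdout_ids=np.sort(perm[n_train : n_train + n_holdout]),
    )
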