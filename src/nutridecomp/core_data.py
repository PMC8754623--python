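"""Domain types, anthropometric classification and CSV I/O.

The package works on child-level survey records: a binary underweight
indicator (or a weight-for-age Z-score, WAZ, from which it is derived),
a set of categorical covariates, a sampling weight and a survey label.
Underweight is defined as WAZ strictly below -2 SD of the reference-
population median, severe underweight strictly below -3 SD.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("nutridecomp")

__all__ = [
    "NutridecompError",
    "InvalidInputError",
    "SchemaViolationError",
    "DegenerateCovariateError",
    "CSVFormatError",
    "ContractError",
    "Variable",
    "Schema",
    "ChildRecord",
    "SurveyDataset",
    "DesignMatrix",
    "classify_waz",
    "classify_waz_array",
    "build_design",
    "read_survey_csv",
    "write_survey_csv",
    "write_results",
]


# ---------------------------------------------------------------------------
# errors

class NutridecompError(Exception):
    """Base class for all package errors."""


class InvalidInputError(NutridecompError):
    """A value violates an operation precondition (e.g. non-finite WAZ)."""


class SchemaViolationError(NutridecompError):
    """A record carries a category label not present in the schema."""


class DegenerateCovariateError(NutridecompError):
    """A modeled categorical variable has fewer than two observed levels."""


class CSVFormatError(NutridecompError):
    """A CSV file cannot be interpreted under the given column map."""


class ContractError(NutridecompError):
    """Inconsistent objects passed between pipeline stages."""


# ---------------------------------------------------------------------------
# schema

@dataclass(frozen=True)
class Variable:
    """One categorical covariate: ordered category labels, reference first
    unless ``reference`` names another category."""

    name: str
    categories: tuple[str, ...]
    reference: str = ""

    def __post_init__(self):
        if len(self.categories) < 2:
            raise SchemaViolationError(
                f"variable {self.name!r} needs >= 2 categories, got {self.categories}"
            )
        if len(set(self.categories)) != len(self.categories):
            raise SchemaViolationError(f"duplicate categories in {self.name!r}")
        ref = self.reference or self.categories[0]
        if ref not in self.categories:
            raise SchemaViolationError(
                f"reference {ref!r} not among categories of {self.name!r}"
            )
        object.__setattr__(self, "reference", ref)

    @property
    def non_reference(self) -> tuple[str, ...]:
        return tuple(c for c in self.categories if c != self.reference)

    def with_reference(self, category: str) -> "Variable":
        return replace(self, reference=category)


@dataclass(frozen=True)
class Schema:
    """Ordered covariate schema shared by every survey in an analysis."""

    variables: tuple[Variable, ...]

    def __post_init__(self):
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SchemaViolationError("duplicate variable names in schema")

    def __iter__(self):
        return iter(self.variables)

    def __len__(self):
        return len(self.variables)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def __getitem__(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def with_reference(self, name: str, category: str) -> "Schema":
        """New schema with a different reference category for one variable."""
        return Schema(tuple(
            v.with_reference(category) if v.name == name else v
            for v in self.variables
        ))

    @property
    def n_design_columns(self) -> int:
        """Intercept plus one dummy per non-reference category."""
        return 1 + sum(len(v.categories) - 1 for v in self.variables)


# ---------------------------------------------------------------------------
# anthropometric classification

def classify_waz(waz: float) -> str:
    """Classify a weight-for-age Z-score.

    Strictly below -3 SD is ``"severe"``, in [-3, -2) is ``"underweight"``,
    -2 and above is ``"normal"``.  The binary underweight indicator used in
    modeling is ``waz < -2``, so severe implies underweight.
    """
    if not math.isfinite(waz):
        raise InvalidInputError(f"WAZ must be finite, got {waz!r}")
    if waz < -3:
        return "severe"
    if waz < -2:
        return "underweight"
    return "normal"


def classify_waz_array(waz) -> np.ndarray:
    """Vectorized :func:`classify_waz`; raises on any non-finite entry."""
    waz = np.asarray(waz, dtype=float)
    if not np.all(np.isfinite(waz)):
        raise InvalidInputError("WAZ values must be finite")
    out = np.full(waz.shape, "normal", dtype=object)
    out[waz < -2] = "underweight"
    out[waz < -3] = "severe"
    return out


# ---------------------------------------------------------------------------
# records and datasets

@dataclass(frozen=True)
class ChildRecord:
    """One child: outcome (WAZ and/or binary), covariates, sampling weight."""

    covariates: Mapping[str, str]
    weight: float
    survey: str
    waz: float | None = None
    underweight: int | None = None

    def __post_init__(self):
        if self.weight < 0:
            raise InvalidInputError(f"weight must be >= 0, got {self.weight}")
        if self.waz is None and self.underweight is None:
            raise InvalidInputError("record needs waz or underweight")
        if self.waz is not None:
            derived = int(self.waz < -2)
            if self.underweight is None:
                object.__setattr__(self, "underweight", derived)
            elif int(self.underweight) != derived:
                raise InvalidInputError(
                    f"underweight={self.underweight} inconsistent with waz={self.waz}"
                )


class SurveyDataset:
    """Child-level records for one survey.

    Backed by a :class:`pandas.DataFrame` with columns ``underweight``,
    ``weight``, optionally ``waz``, and one string column per schema
    variable.  ``n_dropped`` counts incomplete rows removed on load.
    """

    def __init__(self, frame: pd.DataFrame, schema: Schema, survey: str,
                 n_dropped: int = 0, validate: bool = True):
        self.frame = frame.reset_index(drop=True)
        self.schema = schema
        self.survey = str(survey)
        self.n_dropped = int(n_dropped)
        if validate:
            self._validate()

    def _validate(self):
        f = self.frame
        for col in ("underweight", "weight"):
            if col not in f.columns:
                raise ContractError(f"dataset frame lacks column {col!r}")
        if (np.asarray(f["weight"], dtype=float) < 0).any():
            raise InvalidInputError("negative sampling weight")
        y = np.asarray(f["underweight"])
        if not np.isin(y, [0, 1]).all():
            raise InvalidInputError("underweight must be 0/1")
        for v in self.schema:
            if v.name not in f.columns:
                raise ContractError(f"dataset frame lacks covariate {v.name!r}")
            seen = set(f[v.name].unique())
            bad = seen - set(v.categories)
            if bad:
                raise SchemaViolationError(
                    f"unknown categories {sorted(bad)} for variable {v.name!r}"
                )

    def __len__(self):
        return len(self.frame)

    @property
    def records(self) -> list[ChildRecord]:
        covs = self.schema.names
        out = []
        for row in self.frame.itertuples(index=False):
            d = row._asdict()
            out.append(ChildRecord(
                covariates={c: d[c] for c in covs},
                weight=float(d["weight"]),
                survey=self.survey,
                waz=float(d["waz"]) if "waz" in d and pd.notna(d["waz"]) else None,
                underweight=int(d["underweight"]),
            ))
        return out

    @classmethod
    def from_records(cls, records: Sequence[ChildRecord], schema: Schema,
                     survey: str | None = None) -> "SurveyDataset":
        if not records:
            raise InvalidInputError("empty record collection")
        labels = {r.survey for r in records}
        if survey is None:
            if len(labels) != 1:
                raise ContractError(f"records span surveys {sorted(labels)}")
            survey = records[0].survey
        rows = []
        for r in records:
            row = dict(r.covariates)
            row["underweight"] = int(r.underweight)
            row["weight"] = float(r.weight)
            if r.waz is not None:
                row["waz"] = float(r.waz)
            rows.append(row)
        return cls(pd.DataFrame(rows), schema, survey)

    def weighted_prevalence(self) -> float:
        """Weighted underweight prevalence as a proportion in [0, 1]."""
        w = np.asarray(self.frame["weight"], dtype=float)
        y = np.asarray(self.frame["underweight"], dtype=float)
        sw = w.sum()
        if sw <= 0:
            raise InvalidInputError("total weight is zero")
        return float((w * y).sum() / sw)


# ---------------------------------------------------------------------------
# design matrix

@dataclass
class DesignMatrix:
    """Dummy-coded design with a leading intercept column.

    ``groups`` maps each categorical variable to the design-column indices
    of its non-reference dummies; ``columns`` are human-readable labels of
    the form ``"variable=Category"`` (``"intercept"`` first).
    """

    values: np.ndarray
    weights: np.ndarray
    outcome: np.ndarray
    groups: dict[str, list[int]]
    columns: list[str]
    schema: Schema | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.outcome = np.asarray(self.outcome, dtype=float)
        n, k = self.values.shape
        if n == 0:
            raise InvalidInputError("design has no rows")
        if not np.all(self.values[:, 0] == 1.0):
            raise ContractError("first design column must be the intercept")
        if len(self.columns) != k:
            raise ContractError("column label count mismatch")

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def weighted_column_means(self) -> np.ndarray:
        w = self.weights
        return (self.values * w[:, None]).sum(axis=0) / w.sum()

    def same_structure(self, other: "DesignMatrix") -> bool:
        return self.columns == other.columns and self.groups == other.groups


def build_design(dataset: SurveyDataset) -> DesignMatrix:
    """Dummy-expand a survey's covariates (reference categories omitted).

    Column order is deterministic: intercept, then schema order, then each
    variable's category order with the reference skipped.  A variable with
    a single observed level would produce a constant column and raises
    :class:`DegenerateCovariateError`.
    """
    f = dataset.frame
    n = len(f)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    groups: dict[str, list[int]] = {}
    for v in dataset.schema:
        observed = set(f[v.name].unique())
        if len(observed) < 2:
            raise DegenerateCovariateError(
                f"variable {v.name!r} has a single observed level {sorted(observed)}"
            )
        idx = []
        vals = f[v.name].to_numpy()
        for cat in v.categories:
            if cat == v.reference:
                continue
            idx.append(len(names))
            names.append(f"{v.name}={cat}")
            cols.append((vals == cat).astype(float))
        groups[v.name] = idx
    values = np.column_stack(cols)
    return DesignMatrix(
        values=values,
        weights=np.asarray(f["weight"], dtype=float),
        outcome=np.asarray(f["underweight"], dtype=float),
        groups=groups,
        columns=names,
        schema=dataset.schema,
    )


# ---------------------------------------------------------------------------
# CSV I/O

_RESERVED = ("waz", "underweight", "weight", "survey")


def read_survey_csv(path, schema: Schema, column_map: Mapping[str, str] | None = None,
                    survey: str | None = None) -> SurveyDataset:
    """Read one survey's child records from a CSV file.

    ``column_map`` maps logical names (``waz``, ``underweight``, ``weight``,
    ``survey`` and each schema variable) to the file's column headers;
    unmapped names default to themselves.  Either a ``waz`` or an
    ``underweight`` column must be present; when only WAZ is given the
    binary indicator is derived (WAZ < -2).  Rows missing the outcome, the
    weight or any schema covariate are dropped and counted in
    ``SurveyDataset.n_dropped``.
    """
    path = Path(path)
    column_map = dict(column_map or {})

    def col(logical: str) -> str:
        return column_map.get(logical, logical)

    try:
        # only empty cells are missing: category labels like "None" or
        # "NA" are legitimate data
        raw = pd.read_csv(path, dtype=str, keep_default_na=False,
                          na_values=[""])
    except pd.errors.EmptyDataError as exc:
        raise CSVFormatError(f"{path}: empty file") from exc
    if raw.empty and raw.columns.empty:
        raise CSVFormatError(f"{path}: no header row")

    needed = [col(v.name) for v in schema] + [col("weight")]
    have_waz = col("waz") in raw.columns
    have_uw = col("underweight") in raw.columns
    if not have_waz and not have_uw:
        raise CSVFormatError(
            f"{path}: neither outcome column {col('waz')!r} nor "
            f"{col('underweight')!r} present"
        )
    for c in needed:
        if c not in raw.columns:
            raise CSVFormatError(f"{path}: missing mapped column {c!r}")

    out = pd.DataFrame()
    for v in schema:
        out[v.name] = raw[col(v.name)]

    def numeric(logical: str) -> pd.Series:
        s = pd.to_numeric(raw[col(logical)], errors="coerce")
        bad = s.isna() & raw[col(logical)].notna() & (raw[col(logical)].str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # 1-based + header line
            raise CSVFormatError(
                f"{path}: non-numeric {logical!r} value "
                f"{raw[col(logical)][bad].iloc[0]!r} at line {row}"
            )
        return s

    out["weight"] = numeric("weight")
    if have_waz:
        out["waz"] = numeric("waz")
    if have_uw:
        out["underweight"] = numeric("underweight")
    elif have_waz:
        out["underweight"] = (out["waz"] < -2).astype(float).where(out["waz"].notna())

    if col("survey") in raw.columns:
        labels = raw[col("survey")].dropna().unique()
        if survey is None:
            if len(labels) != 1:
                raise CSVFormatError(f"{path}: multiple survey labels {sorted(labels)}")
            survey = str(labels[0])
    if survey is None:
        survey = path.stem

    complete = out["weight"].notna() & out["underweight"].notna()
    for v in schema:
        complete &= out[v.name].notna()
    n_dropped = int((~complete).sum())
    out = out.loc[complete].copy()
    if out.empty:
        raise CSVFormatError(f"{path}: no complete rows")
    out["underweight"] = out["underweight"].astype(int)
    if n_dropped:
        logger.info("%s: dropped %d incomplete row(s)", path, n_dropped)
    return SurveyDataset(out, schema, survey, n_dropped=n_dropped)


def write_survey_csv(dataset: SurveyDataset, path) -> None:
    """Write a survey back to CSV in the canonical column layout."""
    f = dataset.frame.copy()
    f["survey"] = dataset.survey
    lead = [c for c in ("survey", "waz", "underweight", "weight") if c in f.columns]
    f = f[lead + [v.name for v in dataset.schema]]
    f.to_csv(path, index=False)


def write_results(table: pd.DataFrame, path) -> None:
    """Write a result table (trend or decomposition shape) to CSV."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
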