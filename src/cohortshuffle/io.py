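"""Cohort schema, table container, and CSV/JSON input-output.

A cohort is a patients-by-features table with two kinds of columns:
binary condition flags (0/1, a subset of which are study endpoints) and
continuous clinical measurements.  The schema fixes which column is
which and, crucially, the *order* of the binary columns: the ordered
tuple of a patient's binary values is the class key used for
stratification, so column order is part of the data model.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CohortSchema",
    "CohortTable",
    "RunReport",
    "SchemaError",
    "ValidationError",
    "read_schema",
    "read_cohort",
    "write_cohort",
    "write_report",
]

#: Origin flag values for rows.
ORIGINAL = "original"
SYNTHETIC = "synthetic"

#: Tokens parsed as a missing cell (case-insensitive, surrounding
#: whitespace ignored).  Missing cells are written back as empty strings.
MISSING_TOKENS = frozenset({"", "na", "nan"})


class SchemaError(ValueError):
    """A file or config does not match the declared cohort schema."""


class ValidationError(ValueError):
    """A cell value violates the schema's domain (e.g. non-0/1 binary)."""


@dataclass(frozen=True)
class CohortSchema:
    """Declares the cohort's columns and their roles.

    Parameters
    ----------
    binary_features:
        Ordered names of the 0/1 condition columns (``B`` of them).
        Their order defines the class key and is preserved everywhere.
    numeric_features:
        Ordered names of the continuous measurement columns (``P``).
    endpoint_features:
        The subset of ``binary_features`` that are study endpoints
        (outcome flags rather than baseline conditions).
    id_column:
        Optional patient-identifier column; carried through unchanged.
    """

    binary_features: tuple[str, ...]
    numeric_features: tuple[str, ...]
    endpoint_features: tuple[str, ...] = ()
    id_column: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "binary_features", tuple(self.binary_features))
        object.__setattr__(self, "numeric_features", tuple(self.numeric_features))
        object.__setattr__(self, "endpoint_features", tuple(self.endpoint_features))
        if not self.binary_features or not self.numeric_features:
            raise SchemaError("binary_features and numeric_features must be non-empty")
        overlap = set(self.binary_features) & set(self.numeric_features)
        if overlap:
            raise SchemaError(f"columns declared both binary and numeric: {sorted(overlap)}")
        for cols in (self.binary_features, self.numeric_features):
            if len(set(cols)) != len(cols):
                raise SchemaError("duplicate column names in schema")
        stray = set(self.endpoint_features) - set(self.binary_features)
        if stray:
            raise SchemaError(f"endpoint features not among binary features: {sorted(stray)}")
        if self.id_column in self.binary_features or self.id_column in self.numeric_features:
            raise SchemaError(f"id_column {self.id_column!r} clashes with a feature column")

    @property
    def n_binary(self) -> int:
        return len(self.binary_features)

    @property
    def n_numeric(self) -> int:
        return len(self.numeric_features)

    @property
    def feature_columns(self) -> tuple[str, ...]:
        """All feature columns in canonical order: binary first, then numeric."""
        return self.binary_features + self.numeric_features

    @property
    def columns(self) -> tuple[str, ...]:
        """Canonical file column order (id column first when declared)."""
        head = (self.id_column,) if self.id_column else ()
        return head + self.feature_columns

    def to_dict(self) -> dict[str, Any]:
        return {
            "binary_features": list(self.binary_features),
            "numeric_features": list(self.numeric_features),
            "endpoint_features": list(self.endpoint_features),
            "id_column": self.id_column,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "CohortSchema":
        try:
            return cls(
                binary_features=tuple(d["binary_features"]),
                numeric_features=tuple(d["numeric_features"]),
                endpoint_features=tuple(d.get("endpoint_features", ())),
                id_column=d.get("id_column"),
            )
        except KeyError as e:  # pragma: no cover - message plumbing
            raise SchemaError(f"schema config missing key {e.args[0]!r}") from e


def read_schema(path: str | Path) -> CohortSchema:
    """Load a :class:`CohortSchema` from a YAML or JSON config file.

    The file holds the keys ``binary_features``, ``numeric_features``,
    ``endpoint_features`` and optionally ``id_column``, either at top
    level or under a ``schema`` block.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(data, Mapping):
        raise SchemaError(f"{path}: expected a mapping at top level")
    if "schema" in data and isinstance(data["schema"], Mapping):
        data = data["schema"]
    return CohortSchema.from_dict(data)


class CohortTable:
    """A patients-by-features table with missingness and row provenance.

    Binary cells are stored as pandas nullable integers (``Int64``) so a
    cell is exactly 0, 1 or missing; numeric cells are float64 with NaN
    for missing.  Every row carries an origin flag (``original`` or
    ``synthetic``); the flag is bookkeeping for deduplication and reports
    and is never written to cohort CSV files.
    """

    def __init__(
        self,
        schema: CohortSchema,
        df: pd.DataFrame,
        origin: Sequence[str] | None = None,
    ) -> None:
        missing_cols = [c for c in schema.columns if c not in df.columns]
        if missing_cols:
            raise SchemaError(f"table missing schema columns: {missing_cols}")
        df = df.loc[:, list(schema.columns)].reset_index(drop=True)
        for col in schema.binary_features:
            vals = pd.array(df[col], dtype="Int64")
            bad = vals.dropna()
            if len(bad) and not ((bad == 0) | (bad == 1)).all():
                raise ValidationError(f"binary column {col!r} has values outside {{0,1}}")
            df[col] = vals
        for col in schema.numeric_features:
            df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        self.schema = schema
        self.df = df
        if origin is None:
            origin = [ORIGINAL] * len(df)
        origin = np.asarray(origin, dtype=object)
        if len(origin) != len(df):
            raise ValueError("origin flag length does not match row count")
        bad_flags = set(origin) - {ORIGINAL, SYNTHETIC}
        if bad_flags:
            raise ValueError(f"unknown origin flags: {sorted(bad_flags)}")
        self.origin = origin

    # -- basic protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        return (
            self.schema == other.schema
            and len(self) == len(other)
            and self.df.equals(other.df)
        )

    def __repr__(self) -> str:
        return (
            f"CohortTable({len(self)} rows, B={self.schema.n_binary}, "
            f"P={self.schema.n_numeric}, missing={int(self.n_missing_cells)})"
        )

    # -- views ---------------------------------------------------------
    @property
    def n_missing_cells(self) -> int:
        return int(self.df[list(self.schema.feature_columns)].isna().sum().sum())

    @property
    def is_complete(self) -> bool:
        return self.n_missing_cells == 0

    def binary_matrix(self) -> pd.DataFrame:
        return self.df[list(self.schema.binary_features)]

    def numeric_matrix(self) -> np.ndarray:
        """The n x P float array of numeric features (NaN where missing)."""
        return self.df[list(self.schema.numeric_features)].to_numpy(dtype=float)

    def copy(self) -> "CohortTable":
        return CohortTable(self.schema, self.df.copy(), self.origin.copy())

    def take(self, indices: Iterable[int]) -> "CohortTable":
        idx = np.fromiter(indices, dtype=int)
        return CohortTable(self.schema, self.df.iloc[idx], self.origin[idx])

    @staticmethod
    def concat(tables: Sequence["CohortTable"]) -> "CohortTable":
        if not tables:
            raise ValueError("nothing to concatenate")
        schema = tables[0].schema
        if any(t.schema != schema for t in tables):
            raise SchemaError("cannot concatenate tables with different schemas")
        df = pd.concat([t.df for t in tables], ignore_index=True)
        origin = np.concatenate([t.origin for t in tables])
        return CohortTable(schema, df, origin)

    def row_keys(self) -> list[tuple]:
        """Full-row identity keys (all B + P feature values, id excluded).

        Used for exact-duplicate detection; binary NA sorts as a distinct
        sentinel so incomplete rows never alias complete ones.
        """
        cols = list(self.schema.feature_columns)
        recs = self.df[cols].itertuples(index=False, name=None)
        return [tuple(None if pd.isna(v) else v for v in r) for r in recs]


@dataclass
class RunReport:
    """Provenance record for one pipeline stage (JSON-serializable).

    ``removed`` maps a filter name to its removal count; for filter
    stages ``n_in == n_out + sum(removed.values())`` is enforced.
    """

    stage: str
    n_in: int | None = None
    n_out: int | None = None
    removed: dict[str, int] = field(default_factory=dict)
    params: dict[str, Any] = field(default_factory=dict)
    hotelling: dict[str, Any] | None = None
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, count in self.removed.items():
            if count < 0:
                raise ValueError(f"negative removal count for {name!r}")
        if self.removed and self.n_in is not None and self.n_out is not None:
            if self.n_in != self.n_out + sum(self.removed.values()):
                raise ValueError(
                    f"report inconsistency: {self.n_in} != "
                    f"{self.n_out} + {sum(self.removed.values())}"
                )

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d


def _parse_cell(token: str, *, binary: bool, col: str, row: int):
    token = token.strip()
    if token.lower() in MISSING_TOKENS:
        return None
    try:
        value = float(token)
    except ValueError:
        raise ValidationError(f"row {row}, column {col!r}: cannot parse {token!r}") from None
    if binary:
        if value not in (0.0, 1.0):
            raise ValidationError(
                f"row {row}, column {col!r}: binary value must be 0 or 1, got {token!r}"
            )
        return int(value)
    return value


def read_cohort(path: str | Path, schema: CohortSchema) -> CohortTable:
    """Read a cohort CSV into a :class:`CohortTable`.

    The header must contain every schema column (extra columns are
    ignored).  Empty cells and the tokens ``NA``/``NaN`` (any case) are
    parsed as missing.  All rows are flagged ``original``.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in schema.columns if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"{path}: header lacks schema columns {missing_cols}")
    data: dict[str, list] = {}
    if schema.id_column:
        data[schema.id_column] = raw[schema.id_column].tolist()
    for col in schema.binary_features:
        data[col] = [
            _parse_cell(v, binary=True, col=col, row=i) for i, v in enumerate(raw[col])
        ]
    for col in schema.numeric_features:
        data[col] = [
            _parse_cell(v, binary=False, col=col, row=i) for i, v in enumerate(raw[col])
        ]
    df = pd.DataFrame(data)
    for col in schema.numeric_features:
        df[col] = df[col].astype(float)
    return CohortTable(schema, df)


def write_cohort(
    table: CohortTable,
    path: str | Path,
    class_ids: Sequence[int] | None = None,
) -> None:
    """Write a cohort to CSV in canonical column order.

    Missing cells become empty fields; ``read_cohort`` of the result
    reproduces the table value-for-value.  When ``class_ids`` is given a
    trailing ``class_id`` column is appended (stratified outputs).
    """
    df = table.df.copy()
    if class_ids is not None:
        if len(class_ids) != len(df):
            raise ValueError("class_ids length does not match row count")
        df["class_id"] = np.asarray(class_ids, dtype=int)
    df.to_csv(path, index=False, na_rep="")


def write_report(report: RunReport | Sequence[RunReport], path: str | Path) -> None:
    """Serialize one report (or a list of stage reports) to JSON."""
    if isinstance(report, RunReport):
        payload: Any = report.to_dict()
    else:
        payload = [r.to_dict() for r in report]
    Path(path).write_text(json.dumps(payload, indent=2, default=float) + "\n")
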