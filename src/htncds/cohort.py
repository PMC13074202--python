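"""Cohort schema, table representation, and CSV round-tripping.

A cohort is a flat patient table with three kinds of variables:

* ``numeric`` — continuous clinical measurements (mmHg, mg/dL, cm, ...);
* ``categorical`` — single-choice labels drawn from a declared category list;
* ``multihot`` — checklist variables where any subset of the declared
  options may be selected simultaneously (stored as a frozenset).

Missingness is explicit: every :class:`CohortTable` carries a boolean mask
aligned cell-for-cell with its values, and the mask — not a sentinel value —
is the single source of truth for what is observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VariableSchema",
    "CohortTable",
    "MissingnessSummary",
    "SchemaError",
    "ParseError",
    "load_schema",
    "save_schema",
    "read_cohort",
    "write_cohort",
    "missingness_summary",
]

KINDS = ("numeric", "categorical", "multihot")

#: serialized form of an *explicitly empty* multihot selection (distinct from
#: the missing token, which marks an unanswered checklist)
EMPTY_MULTIHOT_TOKEN = "-"
MULTIHOT_SEP = "|"


class SchemaError(ValueError):
    """Raised when a schema or a table violates its declared structure."""


class ParseError(ValueError):
    """Raised for cell values that cannot be parsed under the declared kind."""


@dataclass(frozen=True)
class VariableSchema:
    """Declaration of a single cohort variable."""

    name: str
    kind: str
    units: str = ""
    plausible_range: tuple[float, float] | None = None
    categories: tuple[str, ...] = ()
    clustering_feature: bool = False
    rule_input: bool = False
    identifier: bool = False

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SchemaError(f"{self.name}: unknown kind {self.kind!r}")
        if self.plausible_range is not None:
            lo, hi = self.plausible_range
            if not lo < hi:
                raise SchemaError(
                    f"{self.name}: plausible_range low must be < high, got {self.plausible_range}"
                )
        if self.kind in ("categorical", "multihot") and not self.categories:
            raise SchemaError(f"{self.name}: {self.kind} variable needs a category list")


def _check_schema(schema: Sequence[VariableSchema]) -> None:
    names = [v.name for v in schema]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise SchemaError(f"duplicate variable names: {dupes}")
    n_id = sum(v.identifier for v in schema)
    if n_id != 1:
        raise SchemaError(f"exactly one identifier variable required, found {n_id}")


@dataclass
class CohortTable:
    """Schema-typed patient table with an explicit missingness mask.

    ``data`` holds one column per schema variable, in schema order; numeric
    columns are float64 (NaN where masked), categorical columns hold strings
    (None where masked) and multihot columns hold frozensets of selected
    options (None where masked).  ``mask`` is True exactly where a cell is
    missing.  ``anomalies`` collects validation findings (e.g. categorical
    values outside the declared list) without coercing the offending cells.
    """

    schema: list[VariableSchema]
    data: pd.DataFrame
    mask: pd.DataFrame
    anomalies: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_schema(self.schema)
        names = [v.name for v in self.schema]
        if list(self.data.columns) != names:
            raise SchemaError("data columns must match schema names in order")
        if list(self.mask.columns) != names or len(self.mask) != len(self.data):
            raise SchemaError("mask must be aligned with data (rows x variables)")
        ids = self.data[self.id_variable].tolist()
        if len(set(ids)) != len(ids):
            raise SchemaError("identifiers are not unique")

    # -- convenience accessors -------------------------------------------------

    @property
    def id_variable(self) -> str:
        return next(v.name for v in self.schema if v.identifier)

    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def n_variables(self) -> int:
        return len(self.schema)

    def variable(self, name: str) -> VariableSchema:
        for v in self.schema:
            if v.name == name:
                return v
        raise KeyError(name)

    def variables(self, kind: str | None = None, clustering: bool | None = None) -> list[str]:
        out = []
        for v in self.schema:
            if kind is not None and v.kind != kind:
                continue
            if clustering is not None and v.clustering_feature != clustering:
                continue
            out.append(v.name)
        return out

    def copy(self) -> "CohortTable":
        return CohortTable(
            schema=list(self.schema),
            data=self.data.copy(),
            mask=self.mask.copy(),
            anomalies=list(self.anomalies),
        )


@dataclass(frozen=True)
class MissingnessSummary:
    total_cells: int
    missing_cells: int
    fraction: float
    per_variable: pd.Series
    per_row: pd.Series


def missingness_summary(cohort: CohortTable) -> MissingnessSummary:
    """Count masked cells overall, per variable, and per row.

    The overall fraction uses the full rows x variables denominator, so an
    identifier column that is never missing dilutes the per-cell rate
    accordingly.  Per-row fractions feed the >50 % record filter.
    """
    mask = cohort.mask.to_numpy()
    total = int(mask.size)
    missing = int(mask.sum())
    return MissingnessSummary(
        total_cells=total,
        missing_cells=missing,
        fraction=missing / total if total else 0.0,
        per_variable=cohort.mask.mean(axis=0),
        per_row=cohort.mask.mean(axis=1),
    )


# -- schema files --------------------------------------------------------------


def load_schema(path: str | Path) -> list[VariableSchema]:
    """Load a schema from a YAML/JSON list of variable declarations."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    schema = []
    for entry in raw:
        rng = entry.get("plausible_range")
        schema.append(
            VariableSchema(
                name=entry["name"],
                kind=entry["kind"],
                units=entry.get("units", ""),
                plausible_range=tuple(rng) if rng else None,
                categories=tuple(entry.get("categories", ())),
                clustering_feature=bool(entry.get("clustering_feature", False)),
                rule_input=bool(entry.get("rule_input", False)),
                identifier=bool(entry.get("identifier", False)),
            )
        )
    _check_schema(schema)
    return schema


def save_schema(schema: Sequence[VariableSchema], path: str | Path) -> None:
    out = []
    for v in schema:
        entry: dict = {"name": v.name, "kind": v.kind}
        if v.units:
            entry["units"] = v.units
        if v.plausible_range:
            entry["plausible_range"] = list(v.plausible_range)
        if v.categories:
            entry["categories"] = list(v.categories)
        for flag in ("clustering_feature", "rule_input", "identifier"):
            if getattr(v, flag):
                entry[flag] = True
        out.append(entry)
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False, allow_unicode=True)


# -- CSV I/O -------------------------------------------------------------------


def _parse_cell(raw: str, var: VariableSchema, row: int, anomalies: list[str]):
    if var.kind == "numeric":
        try:
            return float(raw)
        except ValueError:
            raise ParseError(
                f"row {row}, column {var.name!r}: cannot parse {raw!r} as numeric"
            ) from None
    if var.kind == "categorical":
        if raw not in var.categories:
            anomalies.append(
                f"row {row}, column {var.name!r}: value {raw!r} outside declared categories"
            )
        return raw
    # multihot
    if raw == EMPTY_MULTIHOT_TOKEN:
        return frozenset()
    opts = raw.split(MULTIHOT_SEP)
    bad = [o for o in opts if o not in var.categories]
    if bad:
        anomalies.append(f"row {row}, column {var.name!r}: unknown options {bad}")
    return frozenset(opts)


def read_cohort(
    path: str | Path,
    schema: Sequence[VariableSchema],
    missing_token: str = "",
) -> CohortTable:
    """Read a cohort CSV, binding columns to the schema by name.

    Empty cells and ``missing_token`` become mask entries.  Categorical
    values outside the declared category list are recorded in
    ``CohortTable.anomalies`` rather than silently coerced; unparseable
    numerics raise a row/column-addressed :class:`ParseError`.
    """
    _check_schema(schema)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    names = [v.name for v in schema]
    missing_cols = sorted(set(names) - set(raw.columns))
    extra_cols = sorted(set(raw.columns) - set(names))
    if missing_cols or extra_cols:
        raise SchemaError(
            f"header mismatch: missing columns {missing_cols}, unexpected columns {extra_cols}"
        )
    anomalies: list[str] = []
    data: dict[str, list] = {}
    mask: dict[str, list] = {}
    for var in schema:
        col_vals, col_mask = [], []
        for row, cell in enumerate(raw[var.name].tolist()):
            if cell == missing_token:
                col_vals.append(np.nan if var.kind == "numeric" else None)
                col_mask.append(True)
            else:
                col_vals.append(_parse_cell(cell, var, row, anomalies))
                col_mask.append(False)
        data[var.name] = col_vals
        mask[var.name] = col_mask
    frame = pd.DataFrame(data, columns=names)
    for var in schema:
        if var.kind == "numeric":
            frame[var.name] = frame[var.name].astype(float)
    return CohortTable(
        schema=list(schema),
        data=frame,
        mask=pd.DataFrame(mask, columns=names, dtype=bool),
        anomalies=anomalies,
    )


def _format_cell(value, var: VariableSchema) -> str:
    if var.kind == "numeric":
        f = float(value)
        return str(int(f)) if f.is_integer() else repr(f)
    if var.kind == "multihot":
        if not value:
            return EMPTY_MULTIHOT_TOKEN
        # deterministic option order from the schema declaration
        return MULTIHOT_SEP.join(o for o in var.categories if o in value)
    return str(value)


def write_cohort(
    cohort: CohortTable,
    path: str | Path,
    missing_token: str = "",
) -> None:
    """Write a cohort CSV; ``read_cohort(write_cohort(x))`` round-trips exactly."""
    names = [v.name for v in cohort.schema]
    lines = [",".join(names)]
    mask = cohort.mask.to_numpy()
    for i in range(cohort.n_rows):
        cells = []
        for j, var in enumerate(cohort.schema):
            if mask[i, j]:
                cells.append(missing_token)
            else:
                cells.append(_format_cell(cohort.data.iat[i, j], var))
        lines.append(",".join(cells))
    try:
        Path(path).write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write cohort to {path}: {exc}") from exc
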