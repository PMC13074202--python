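"""Record filtering, unit repair, imputation, encoding and standardization.

The stage order is fixed and mirrors how a clinical table must be cleaned
before distance-based analysis: incomplete records are dropped first, unit
errors repaired next (so imputation distances are not distorted by
meter-scale heights), implausible values flagged but never deleted, then
numeric cells are KNN-imputed, categorical cells mode-imputed, blank
checklist entries mapped to explicit zeros, and finally the table is
encoded/standardized.  :func:`run_preprocessing` enforces that order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .cohort import CohortTable

__all__ = [
    "PreprocessConfig",
    "PreprocessReport",
    "StandardizedMatrix",
    "filter_incomplete_records",
    "correct_height_units",
    "flag_implausible",
    "impute_numeric_knn",
    "impute_categorical_mode",
    "impute_numeric_median",
    "multihot_fill_zero",
    "zscore_standardize",
    "one_hot_encode",
    "pearson_correlations",
    "run_preprocessing",
]


@dataclass
class PreprocessConfig:
    """Tunable preprocessing parameters.

    ``max_missing_fraction`` is strict: a record is dropped only when its
    missing fraction exceeds the threshold ("more than 50 %"), so exactly
    half-missing rows are kept.  ``knn_k`` may be the string ``"sqrt"`` to
    use round(sqrt(n)) neighbors.  Heights below ``meters_cutoff`` are taken
    to be meters: no adult height is ambiguous across 3.0 under either unit.
    """

    max_missing_fraction: float = 0.5
    knn_k: int | str = "sqrt"
    meters_cutoff: float = 3.0
    height_variable: str = "height_cm"

    def __post_init__(self) -> None:
        if not 0 < self.max_missing_fraction < 1:
            raise ValueError("max_missing_fraction must be in (0, 1)")
        if isinstance(self.knn_k, str):
            if self.knn_k != "sqrt":
                raise ValueError("knn_k must be an integer or 'sqrt'")
        elif self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")

    def resolve_k(self, n_rows: int) -> int:
        if self.knn_k == "sqrt":
            return max(1, round(math.sqrt(n_rows)))
        return int(self.knn_k)


@dataclass
class PreprocessReport:
    rows_dropped: int = 0
    dropped_identifiers: list = field(default_factory=list)
    unit_corrections: int = 0
    unit_correction_rows: list = field(default_factory=list)
    numeric_cells_imputed: int = 0
    categorical_cells_imputed: dict[str, int] = field(default_factory=dict)
    categorical_imputed_value: dict[str, str] = field(default_factory=dict)
    multihot_cells_zeroed: int = 0
    out_of_range_flags: list = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def merge(self, other: "PreprocessReport") -> "PreprocessReport":
        return PreprocessReport(
            rows_dropped=self.rows_dropped + other.rows_dropped,
            dropped_identifiers=self.dropped_identifiers + other.dropped_identifiers,
            unit_corrections=self.unit_corrections + other.unit_corrections,
            unit_correction_rows=self.unit_correction_rows + other.unit_correction_rows,
            numeric_cells_imputed=self.numeric_cells_imputed + other.numeric_cells_imputed,
            categorical_cells_imputed={**self.categorical_cells_imputed,
                                       **other.categorical_cells_imputed},
            categorical_imputed_value={**self.categorical_imputed_value,
                                       **other.categorical_imputed_value},
            multihot_cells_zeroed=self.multihot_cells_zeroed + other.multihot_cells_zeroed,
            out_of_range_flags=self.out_of_range_flags + other.out_of_range_flags,
            notes=self.notes + other.notes,
        )


@dataclass
class StandardizedMatrix:
    """Z-scored numeric matrix with the statistics needed to invert it."""

    values: np.ndarray
    columns: list[str]
    means: np.ndarray
    sds: np.ndarray
    row_ids: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.columns, index=self.row_ids)

    def inverse(self) -> np.ndarray:
        return self.values * self.sds + self.means


class UnimputableError(ValueError):
    """A variable has no observed values to impute from."""


def filter_incomplete_records(
    cohort: CohortTable, config: PreprocessConfig | None = None
) -> tuple[CohortTable, PreprocessReport]:
    """Drop records whose missing fraction strictly exceeds the threshold."""
    config = config or PreprocessConfig()
    frac = cohort.mask.mean(axis=1)
    drop = frac > config.max_missing_fraction
    kept = cohort.copy()
    kept.data = cohort.data.loc[~drop].reset_index(drop=True)
    kept.mask = cohort.mask.loc[~drop].reset_index(drop=True)
    report = PreprocessReport(
        rows_dropped=int(drop.sum()),
        dropped_identifiers=cohort.data.loc[drop, cohort.id_variable].tolist(),
    )
    if kept.n_rows == 0:
        report.notes.append("all records removed by missingness filter")
    return kept, report


def correct_height_units(
    cohort: CohortTable, config: PreprocessConfig | None = None
) -> tuple[CohortTable, PreprocessReport]:
    """Multiply heights recorded in meters (values below the cutoff) by 100."""
    config = config or PreprocessConfig()
    var = config.height_variable
    if var not in cohort.data.columns:
        raise KeyError(f"height variable {var!r} not in schema")
    out = cohort.copy()
    vals = out.data[var].to_numpy(copy=True)
    observed = ~out.mask[var].to_numpy()
    meters = observed & (vals < config.meters_cutoff)
    vals[meters] = vals[meters] * 100.0
    out.data[var] = vals
    rows = np.flatnonzero(meters)
    return out, PreprocessReport(
        unit_corrections=int(meters.sum()),
        unit_correction_rows=out.data.loc[rows, out.id_variable].tolist(),
    )


def flag_implausible(cohort: CohortTable) -> PreprocessReport:
    """Flag values outside declared plausible ranges; never delete them."""
    flags = []
    for var in cohort.schema:
        if var.kind != "numeric" or var.plausible_range is None:
            continue
        lo, hi = var.plausible_range
        vals = cohort.data[var.name].to_numpy()
        observed = ~cohort.mask[var.name].to_numpy()
        bad = observed & ((vals < lo) | (vals > hi))
        for i in np.flatnonzero(bad):
            flags.append(
                {
                    "row": int(i),
                    "identifier": cohort.data.at[i, cohort.id_variable],
                    "variable": var.name,
                    "value": float(vals[i]),
                    "plausible_range": [lo, hi],
                }
            )
    return PreprocessReport(out_of_range_flags=flags)


def impute_numeric_knn(
    cohort: CohortTable, config: PreprocessConfig | None = None
) -> tuple[CohortTable, PreprocessReport]:
    """Fill missing numeric cells with the mean of the k nearest records.

    Distances are Euclidean over the mutually observed, z-scaled numeric
    coordinates, rescaled by sqrt(total dims / observed dims) (the standard
    partial-distance convention); records missing the target variable do
    not donate.  ``k = round(sqrt(n))`` under the ``"sqrt"`` sentinel.
    Observed cells are never altered.
    """
    config = config or PreprocessConfig()
    num_vars = cohort.variables(kind="numeric")
    out = cohort.copy()
    X = out.data[num_vars].to_numpy(dtype=float, copy=True)
    miss = out.mask[num_vars].to_numpy()
    n_missing = int(miss.sum())
    if n_missing == 0:
        return out, PreprocessReport()
    empty = [v for v, all_missing in zip(num_vars, miss.all(axis=0)) if all_missing]
    if empty:
        raise UnimputableError(f"variables with no observed values: {empty}")

    means = np.nanmean(X, axis=0)
    sds = np.nanstd(X, axis=0)
    sds[sds == 0] = 1.0
    Z = (X - means) / sds
    k = config.resolve_k(len(X))
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    Z_filled = imputer.fit_transform(Z)
    X_filled = Z_filled * sds + means
    X_filled[~miss] = X[~miss]  # guarantee observed cells untouched

    out.data[num_vars] = X_filled
    out.mask[num_vars] = False
    return out, PreprocessReport(numeric_cells_imputed=n_missing)


def impute_numeric_median(cohort: CohortTable) -> tuple[CohortTable, PreprocessReport]:
    """Median substitution — the sensitivity comparator for KNN imputation."""
    num_vars = cohort.variables(kind="numeric")
    out = cohort.copy()
    X = out.data[num_vars].to_numpy(dtype=float, copy=True)
    miss = out.mask[num_vars].to_numpy()
    empty = [v for v, all_missing in zip(num_vars, miss.all(axis=0)) if all_missing]
    if empty:
        raise UnimputableError(f"variables with no observed values: {empty}")
    med = np.nanmedian(X, axis=0)
    X[miss] = np.broadcast_to(med, X.shape)[miss]
    out.data[num_vars] = X
    out.mask[num_vars] = False
    return out, PreprocessReport(numeric_cells_imputed=int(miss.sum()))


def impute_categorical_mode(cohort: CohortTable) -> tuple[CohortTable, PreprocessReport]:
    """Fill missing categorical cells with the most frequent observed category.

    Frequency ties break by schema category order (deterministic, logged).
    """
    out = cohort.copy()
    report = PreprocessReport()
    for var in out.schema:
        if var.kind != "categorical" or var.identifier:
            continue
        col_mask = out.mask[var.name]
        n_miss = int(col_mask.sum())
        if n_miss == 0:
            continue
        observed = out.data.loc[~col_mask, var.name]
        if observed.empty:
            raise UnimputableError(f"variable {var.name!r} has no observed values")
        counts = observed.value_counts()
        top = counts.max()
        tied = [c for c in var.categories if counts.get(c, 0) == top]
        mode = tied[0] if tied else counts.idxmax()
        if len(tied) > 1:
            report.notes.append(
                f"{var.name}: mode tie between {tied}, chose {mode!r} by schema order"
            )
        idx = np.flatnonzero(col_mask.to_numpy())
        out.data.iloc[idx, out.data.columns.get_loc(var.name)] = mode
        out.mask[var.name] = False
        report.categorical_cells_imputed[var.name] = n_miss
        report.categorical_imputed_value[var.name] = mode
    return out, report


def multihot_fill_zero(cohort: CohortTable) -> tuple[CohortTable, PreprocessReport]:
    """Interpret blank checklist entries as 'nothing selected' (all-zero)."""
    out = cohort.copy()
    zeroed = 0
    for var in out.schema:
        if var.kind != "multihot":
            continue
        col_mask = out.mask[var.name]
        idx = np.flatnonzero(col_mask.to_numpy())
        zeroed += len(idx)
        col = out.data.columns.get_loc(var.name)
        for i in idx:
            out.data.iat[i, col] = frozenset()
        out.mask[var.name] = False
    return out, PreprocessReport(multihot_cells_zeroed=zeroed)


def zscore_standardize(cohort: CohortTable, variables: list[str]) -> StandardizedMatrix:
    """Column-wise (x - mean)/sd with the population (n) denominator.

    Constant columns are emitted as zeros with a warning rather than NaN.
    """
    for name in variables:
        if cohort.variable(name).kind != "numeric":
            raise TypeError(f"variable {name!r} is not numeric")
        if cohort.mask[name].any():
            raise ValueError(f"variable {name!r} still has missing cells; impute first")
    X = cohort.data[variables].to_numpy(dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0)  # population sd (ddof=0)
    const = sds == 0
    if const.any():
        warnings.warn(
            f"constant columns standardized to zeros: {[v for v, c in zip(variables, const) if c]}"
        )
    safe = np.where(const, 1.0, sds)
    Z = (X - means) / safe
    Z[:, const] = 0.0
    return StandardizedMatrix(
        values=Z,
        columns=list(variables),
        means=means,
        sds=sds,
        row_ids=cohort.data[cohort.id_variable].tolist(),
    )


def one_hot_encode(cohort: CohortTable) -> tuple[pd.DataFrame, list[str]]:
    """Expand categorical/multihot variables into indicator columns.

    One indicator per (variable, category) declared in the schema; multihot
    variables emit one indicator per option; numeric variables pass through.
    The column registry is schema-ordered and reproducible.
    """
    cols: dict[str, np.ndarray] = {}
    registry: list[str] = []
    for var in cohort.schema:
        if var.identifier:
            continue
        if var.kind == "numeric":
            cols[var.name] = cohort.data[var.name].to_numpy(dtype=float)
            registry.append(var.name)
        elif var.kind == "categorical":
            if cohort.mask[var.name].any():
                raise ValueError(f"categorical {var.name!r} has missing cells; impute first")
            values = cohort.data[var.name].to_numpy()
            for cat in var.categories:
                name = f"{var.name}={cat}"
                cols[name] = (values == cat).astype(float)
                registry.append(name)
        else:
            sets = cohort.data[var.name].tolist()
            masked = cohort.mask[var.name].to_numpy()
            for opt in var.categories:
                name = f"{var.name}={opt}"
                cols[name] = np.array(
                    [0.0 if m or s is None else float(opt in s)
                     for s, m in zip(sets, masked)]
                )
                registry.append(name)
    frame = pd.DataFrame(cols, columns=registry)
    frame.index = cohort.data[cohort.id_variable].tolist()
    return frame, registry


def pearson_correlations(matrix: StandardizedMatrix) -> pd.DataFrame:
    """Pearson correlation grid over the standardized columns."""
    if matrix.values.shape[0] < 2:
        raise ValueError("need at least 2 rows for correlations")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant columns
        corr = np.corrcoef(matrix.values, rowvar=False)
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 1.0)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=matrix.columns, columns=matrix.columns)


def run_preprocessing(
    cohort: CohortTable,
    config: PreprocessConfig | None = None,
    numeric_imputer: str = "knn",
) -> tuple[CohortTable, PreprocessReport]:
    """The fixed Phase-2 pipeline: filter -> unit repair -> plausibility flags
    -> numeric imputation -> categorical mode -> multihot zero-fill.

    After this the table has zero masked cells.  ``numeric_imputer`` may be
    ``"median"`` for the sensitivity comparison.
    """
    config = config or PreprocessConfig()
    table, report = filter_incomplete_records(cohort, config)
    table, rep = correct_height_units(table, config)
    report = report.merge(rep)
    report = report.merge(flag_implausible(table))
    if numeric_imputer == "knn":
        table, rep = impute_numeric_knn(table, config)
    elif numeric_imputer == "median":
        table, rep = impute_numeric_median(table)
    else:
        raise ValueError(f"unknown numeric imputer {numeric_imputer!r}")
    report = report.merge(rep)
    table, rep = impute_categorical_mode(table)
    report = report.merge(rep)
    table, rep = multihot_fill_zero(table)
    report = report.merge(rep)
    return table, report
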