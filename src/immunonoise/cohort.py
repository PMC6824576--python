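"""Cohort table container and tabular I/O.

A cohort is a dense patients x parameters matrix of continuous immunologic
measurements plus one group label per patient (EOP, LOP or VALIDATION).
Every analysis stage of the package consumes and produces this container.

Input files are complete-case by contract: a missing cell is a load error,
never silently imputed, because every downstream statistic (entropy counts,
clustering likelihoods, LOF densities) assumes complete columns.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ALLOWED_GROUPS = frozenset({"EOP", "LOP", "VALIDATION"})

#: discovery set = the two labelled groups the classifiers are trained on
DISCOVERY_GROUPS = frozenset({"EOP", "LOP"})


class CohortLoadError(ValueError):
    """Raised when a cohort file violates the input contract."""


@dataclass
class CohortTable:
    """Patients x parameters matrix with ids and per-patient group labels."""

    patient_ids: list[str]
    parameter_names: list[str]
    values: np.ndarray  # shape (n_patients, n_parameters), float
    group_labels: list[str]

    def __post_init__(self):
        self.patient_ids = [str(p) for p in self.patient_ids]
        self.parameter_names = [str(p) for p in self.parameter_names]
        self.group_labels = [str(g) for g in self.group_labels]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise CohortLoadError("values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.patient_ids) != n:
            raise CohortLoadError(
                f"{len(self.patient_ids)} patient ids for {n} rows")
        if len(self.group_labels) != n:
            raise CohortLoadError(
                f"{len(self.group_labels)} labels for {n} rows")
        if len(self.parameter_names) != p:
            raise CohortLoadError(
                f"{len(self.parameter_names)} parameter names for {p} columns")
        if len(set(self.patient_ids)) != n:
            dupes = sorted({x for x in self.patient_ids
                            if self.patient_ids.count(x) > 1})
            raise CohortLoadError(f"duplicate patient ids: {dupes}")
        if len(set(self.parameter_names)) != p:
            raise CohortLoadError("duplicate parameter names")
        bad = sorted(set(self.group_labels) - ALLOWED_GROUPS)
        if bad:
            raise CohortLoadError(
                f"unknown group labels {bad}; allowed: {sorted(ALLOWED_GROUPS)}")
        if n and p and not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise CohortLoadError(
                "missing or non-finite value at patient "
                f"{self.patient_ids[r]!r}, parameter "
                f"{self.parameter_names[c]!r} (complete-case input required)")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_parameters(self) -> int:
        return self.values.shape[1]

    def group_sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for g in self.group_labels:
            out[g] = out.get(g, 0) + 1
        return out

    def column(self, parameter: str) -> np.ndarray:
        return self.values[:, self.parameter_names.index(parameter)]

    def matrix(self, parameters: Sequence[str] | None = None) -> np.ndarray:
        if parameters is None:
            return self.values.copy()
        idx = [self.parameter_names.index(p) for p in parameters]
        return self.values[:, idx].copy()

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.parameter_names)
        df.insert(0, "patient_id", self.patient_ids)
        df["group"] = self.group_labels
        return df

    def copy(self) -> "CohortTable":
        return replace(
            self,
            patient_ids=list(self.patient_ids),
            parameter_names=list(self.parameter_names),
            values=self.values.copy(),
            group_labels=list(self.group_labels),
        )


def _format_from_path(path: str, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in {"csv", "tsv", "xlsx"}:
            raise CohortLoadError(f"unsupported format {fmt!r}")
        return fmt
    ext = os.path.splitext(str(path))[1].lower().lstrip(".")
    if ext in {"csv", "tsv", "xlsx"}:
        return ext
    raise CohortLoadError(
        f"cannot infer format from {path!r}; pass format explicitly")


def read_cohort(
    path,
    format: str | None = None,
    label_column: str = "group",
    id_column: str = "patient_id",
    sheet_name: int | str = 0,
    column_map: dict[str, str] | None = None,
) -> CohortTable:
    """Read a cohort table from CSV, TSV or XLSX.

    Layout convention: first column = patient id, one numeric column per
    parameter, one label column. ``column_map`` optionally renames file
    columns (file name -> desired name) before validation, so files using
    display names or bespoke headers can be loaded without editing them.
    """
    fmt = _format_from_path(path, format)
    if not os.path.exists(path):
        raise CohortLoadError(f"file not found: {path}")
    if fmt == "xlsx":
        df = pd.read_excel(path, sheet_name=sheet_name)
    else:
        df = pd.read_csv(path, sep="," if fmt == "csv" else "\t")
    if column_map:
        df = df.rename(columns=column_map)
        # the map may rename the id/label columns themselves
        id_column = column_map.get(id_column, id_column)
        label_column = column_map.get(label_column, label_column)
    if id_column not in df.columns:
        # fall back to the positional convention: first column holds the ids
        df = df.rename(columns={df.columns[0]: id_column})
    if label_column not in df.columns:
        raise CohortLoadError(f"label column {label_column!r} not in file")
    param_cols = [c for c in df.columns if c not in (id_column, label_column)]
    ids = df[id_column].astype(str).tolist()
    labels = df[label_column].astype(str).str.strip().str.upper().tolist()
    n = len(df)
    vals = np.empty((n, len(param_cols)), dtype=float)
    for j, c in enumerate(param_cols):
        col = pd.to_numeric(df[c], errors="coerce")
        bad = col.isna() & df[c].notna()
        if bad.any():
            r = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortLoadError(
                f"non-numeric value {df[c].iloc[r]!r} at row {r} "
                f"(patient {ids[r]!r}), column {c!r}")
        vals[:, j] = col.to_numpy(dtype=float)
    return CohortTable(
        patient_ids=ids,
        parameter_names=[str(c) for c in param_cols],
        values=vals,
        group_labels=labels,
    )


def write_cohort(cohort: CohortTable, path, format: str | None = None) -> None:
    """Write a cohort so that :func:`read_cohort` round-trips it losslessly."""
    fmt = _format_from_path(path, format)
    df = cohort.to_dataframe()
    if fmt == "xlsx":
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False, sep="," if fmt == "csv" else "\t")


def subset_by_group(cohort: CohortTable, groups: Iterable[str]) -> CohortTable:
    """Row-filter a cohort to the given group labels, preserving order."""
    groups = set(groups)
    if not groups:
        raise ValueError("groups must be non-empty")
    bad = sorted(groups - ALLOWED_GROUPS)
    if bad:
        raise ValueError(f"unknown groups: {bad}")
    keep = [i for i, g in enumerate(cohort.group_labels) if g in groups]
    if not keep:
        raise ValueError(f"no patients in groups {sorted(groups)}")
    return CohortTable(
        patient_ids=[cohort.patient_ids[i] for i in keep],
        parameter_names=list(cohort.parameter_names),
        values=cohort.values[keep, :],
        group_labels=[cohort.group_labels[i] for i in keep],
    )
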