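"""CSV/JSON/YAML artifact input-output.

Fixed CSV dialect throughout: UTF-8, comma separator, dot decimal, empty
cell = missing value, first column ``patient_id``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortTable
from .errors import DataValidationError
from .evolution import CoreHull
from .variables import VariableSpec, read_variable_specs  # noqa: F401 (re-export)


def read_cohort(
    path: str | Path, specs: list[VariableSpec], timepoint: str
) -> CohortTable:
    """Read a raw cohort CSV, validating ids, columns and raw ranges."""
    df = pd.read_csv(path)
    if df.columns[0] != "patient_id":
        raise DataValidationError(f"{path}: first column must be 'patient_id'")
    if df["patient_id"].duplicated().any():
        dup = df["patient_id"][df["patient_id"].duplicated()].iloc[0]
        raise DataValidationError(f"{path}: duplicated patient_id {dup!r}")
    df = df.set_index("patient_id")
    expected = [s.name for s in specs]
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise DataValidationError(f"{path}: unknown variable {unknown[0]!r}")
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing variable {missing[0]!r}")
    df = df[expected].astype(float)
    for spec in specs:
        col = df[spec.name].dropna()
        bad = col[(col < spec.raw_min) | (col > spec.raw_max)]
        if len(bad):
            raise DataValidationError(
                f"{path}: value {bad.iloc[0]} out of range "
                f"[{spec.raw_min}, {spec.raw_max}] at patient {bad.index[0]!r}, "
                f"variable {spec.name!r}"
            )
    return CohortTable(timepoint, df, specs)


def read_standardized(
    path: str | Path, specs: list[VariableSpec], timepoint: str
) -> CohortTable:
    """Read a standardized (z-scored) table: no raw-range validation applies."""
    df = pd.read_csv(path)
    if df.columns[0] != "patient_id":
        raise DataValidationError(f"{path}: first column must be 'patient_id'")
    if df["patient_id"].duplicated().any():
        dup = df["patient_id"][df["patient_id"].duplicated()].iloc[0]
        raise DataValidationError(f"{path}: duplicated patient_id {dup!r}")
    df = df.set_index("patient_id")
    expected = [s.name for s in specs]
    if sorted(df.columns) != sorted(expected):
        raise DataValidationError(f"{path}: variables do not match the spec file")
    return CohortTable(timepoint, df[expected].astype(float), specs, standardized=True)


def write_cohort(table: CohortTable, path: str | Path) -> None:
    table.data.to_csv(path, index_label="patient_id", na_rep="")


def write_labels(labels: pd.Series, path: str | Path, column: str) -> None:
    labels.rename(column).to_csv(path, index_label="patient_id")


def read_labels(path: str | Path, column: str) -> pd.Series:
    df = pd.read_csv(path).set_index("patient_id")
    if column not in df.columns:
        raise DataValidationError(f"{path}: missing column {column!r}")
    return df[column]


def hulls_to_json(hulls: dict[int, CoreHull], path: str | Path) -> None:
    """Serialize core hulls as GeoJSON-style polygon records."""
    records = []
    for c in sorted(hulls):
        h = hulls[c]
        records.append(
            {
                "phenotype": int(h.phenotype),
                "timepoint": h.timepoint,
                "medoid_id": str(h.medoid_id),
                "n_core_members": len(h.member_ids),
                "area": float(h.area),
                "polygon": {
                    "type": "Polygon",
                    "coordinates": [np.asarray(h.vertices, dtype=float).tolist()],
                },
            }
        )
    Path(path).write_text(json.dumps(records, indent=2))


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=False))


def read_manifest(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
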