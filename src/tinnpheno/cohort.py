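"""The ``CohortTable`` container: patients x variables at one timepoint."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataValidationError
from .variables import VariableSpec

TIMEPOINTS = ("t0", "t1")


@dataclass
class CohortTable:
    """A patients-by-variables score matrix at a single timepoint.

    ``data`` is indexed by patient id; its columns follow ``specs`` order.
    ``standardized`` marks whether values are on the z-score scale (in which
    case all values must be finite) or the raw questionnaire scale (in which
    case empty cells encode missing answers).
    """

    timepoint: str
    data: pd.DataFrame
    specs: list[VariableSpec] = field(repr=False)
    standardized: bool = False

    def __post_init__(self):
        if self.timepoint not in TIMEPOINTS:
            raise DataValidationError(f"unknown timepoint {self.timepoint!r}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate patient ids: {dupes[:5]}")
        expected = [s.name for s in self.specs]
        if list(self.data.columns) != expected:
            raise DataValidationError(
                "column order does not match variable specs "
                f"(first mismatch near {next((c for c, e in zip(self.data.columns, expected) if c != e), '<length>')!r})"
            )
        if self.standardized and not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise DataValidationError("standardized table contains non-finite values")

    @property
    def patient_ids(self) -> pd.Index:
        return self.data.index

    @property
    def variable_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_patients(self) -> int:
        return len(self.data)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def spec_for(self, name: str) -> VariableSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def with_data(self, data: pd.DataFrame, **changes) -> "CohortTable":
        """Copy with replaced data (and optionally other fields)."""
        return replace(self, data=data, **changes)

    def subset(self, patient_ids) -> "CohortTable":
        missing = [p for p in patient_ids if p not in self.data.index]
        if missing:
            raise DataValidationError(f"unknown patient ids: {missing[:5]}")
        return self.with_data(self.data.loc[patient_ids])

    def equals(self, other: "CohortTable") -> bool:
        return (
            self.timepoint == other.timepoint
            and self.standardized == other.standardized
            and self.data.equals(other.data)
        )


def check_aligned(a: CohortTable, b: CohortTable) -> None:
    """Raise unless two tables share identical patients (order included) and variables."""
    if a.variable_names != b.variable_names:
        raise DataValidationError("tables have different variables")
    if not a.patient_ids.equals(b.patient_ids):
        raise DataValidationError("tables have different patient ids or ordering")
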