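"""Reverse-coding, completer filtering and z-standardization.

Higher-is-better variables are reverse-coded (``new = raw_max - old``) so
that higher always means higher disease burden; reversed variables get a
``*`` name suffix. Analysis is restricted to patients with complete data at
both timepoints. Each variable is then z-scored with mean/SD estimated on
the baseline completer table (sample SD, denominator n-1) and the same
scaling is applied to the post-treatment table, so changes live on a single
scale and a score decrease reads as improvement.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import CohortTable, check_aligned
from .errors import DataValidationError
from .variables import VariableSpec


@dataclass(frozen=True)
class AttritionCounts:
    """Staged completeness counts: enrolled -> complete at t0 -> complete at both."""

    total: int
    complete_t0: int
    complete_both: int


def reverse_code(values, raw_max: float):
    """Element-wise ``raw_max - value`` (the reverse-coding formula)."""
    return raw_max - np.asarray(values, dtype=float)


def reverse_code_table(table: CohortTable) -> CohortTable:
    """Reverse-code every higher-is-better variable; rename it with a ``*`` suffix.

    Raises if any value exceeds its declared raw range (names patient and
    variable). Already-reversed specs (polarity higher-is-worse) pass through.
    """
    data = table.data.copy()
    new_specs: list[VariableSpec] = []
    for spec in table.specs:
        col = data[spec.name]
        finite = col.dropna()
        bad = finite[(finite < spec.raw_min) | (finite > spec.raw_max)]
        if len(bad):
            pid, val = bad.index[0], bad.iloc[0]
            raise DataValidationError(
                f"patient {pid!r}, variable {spec.name!r}: value {val} outside "
                f"[{spec.raw_min}, {spec.raw_max}]"
            )
        if spec.polarity == "higher-is-better":
            data[spec.name] = reverse_code(col.to_numpy(), spec.raw_max)
            new_specs.append(
                replace(spec, name=spec.reversed_name, polarity="higher-is-worse")
            )
        else:
            new_specs.append(spec)
    data.columns = [s.name for s in new_specs]
    return CohortTable(table.timepoint, data, new_specs, standardized=table.standardized)


def filter_complete(
    t0: CohortTable, t1: CohortTable
) -> tuple[CohortTable, CohortTable, AttritionCounts]:
    """Keep patients with no missing value at either timepoint.

    Returns the two completer tables (identical patient set, identical order:
    t0 order) and the staged counts. ``total`` counts every patient seen at
    either timepoint; ``complete_t0`` those answering everything at baseline;
    ``complete_both`` those additionally present and complete at t1.
    """
    if [s.name for s in t0.specs] != [s.name for s in t1.specs]:
        raise DataValidationError("t0 and t1 have different variable specs")
    total = len(t0.patient_ids.union(t1.patient_ids))
    complete_t0_ids = t0.data.index[t0.data.notna().all(axis=1)]
    t1_complete = t1.data.index[t1.data.notna().all(axis=1)]
    both_ids = complete_t0_ids[complete_t0_ids.isin(t1_complete)]
    counts = AttritionCounts(total, len(complete_t0_ids), len(both_ids))
    if len(both_ids) == 0:
        raise DataValidationError("no patient is complete at both timepoints")
    return t0.subset(both_ids), t1.subset(both_ids), counts


@dataclass(frozen=True)
class ScalingModel:
    """Per-variable mean and sample SD estimated from the baseline completer table."""

    mean: pd.Series
    sd: pd.Series

    def __post_init__(self):
        if (self.sd <= 0).any():
            bad = self.sd.index[self.sd <= 0][0]
            raise DataValidationError(
                f"variable {bad!r} has zero variance and cannot be z-scored"
            )


def fit_scaling(t0: CohortTable) -> ScalingModel:
    """Estimate per-variable mean and SD (ddof=1) on the baseline completer table."""
    mean = t0.data.mean()
    sd = t0.data.std(ddof=1)
    zero = sd.index[~(sd > 0)]
    if len(zero):
        raise DataValidationError(
            f"variable {zero[0]!r} has zero variance and cannot be z-scored"
        )
    return ScalingModel(mean=mean, sd=sd)


def apply_scaling(table: CohortTable, model: ScalingModel) -> CohortTable:
    """z-score every variable: ``(value - mean) / sd`` with the fitted parameters."""
    if list(table.data.columns) != list(model.mean.index):
        raise DataValidationError("table variables do not match the scaling model")
    data = (table.data - model.mean) / model.sd
    return table.with_data(data, standardized=True)


def preprocess(
    t0_raw: CohortTable, t1_raw: CohortTable
) -> tuple[CohortTable, CohortTable, AttritionCounts, ScalingModel]:
    """Full preprocessing chain: reverse-code, filter completers, z-score.

    The scaling model is fitted on the baseline completers and applied
    unchanged to the t1 table.
    """
    t0_rc = reverse_code_table(t0_raw)
    t1_rc = reverse_code_table(t1_raw)
    t0_c, t1_c, counts = filter_complete(t0_rc, t1_rc)
    model = fit_scaling(t0_c)
    t0_std = apply_scaling(t0_c, model)
    t1_std = apply_scaling(t1_c, model)
    check_aligned(t0_std, t1_std)
    return t0_std, t1_std, counts, model
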