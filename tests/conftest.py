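"""Shared fixtures: generic standardized tables and session-scoped recovery runs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tinnpheno import (
    CohortTable,
    SilhouettePAM,
    VariableSpec,
    compute_deltas,
    generate_cohort,
    preprocess,
    recovery_config,
)
from tinnpheno.variables import CATEGORIES


def generic_specs(n_vars: int, raw_max: float = 10.0) -> list[VariableSpec]:
    """Plain continuous higher-is-worse specs for matrix-driven tests."""
    return [
        VariableSpec(
            name=f"v{i:02d}",
            questionnaire="QX",
            category=CATEGORIES[i % len(CATEGORIES)],
            kind="continuous",
            polarity="higher-is-worse",
            raw_min=0.0,
            raw_max=raw_max,
        )
        for i in range(n_vars)
    ]


def make_table(X, timepoint="t0", standardized=True, ids=None, raw_max=10.0) -> CohortTable:
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if ids is None:
        ids = [f"P{i:04d}" for i in range(1, n + 1)]
    specs = generic_specs(p, raw_max=raw_max)
    df = pd.DataFrame(X, index=pd.Index(ids, name="patient_id"),
                      columns=[s.name for s in specs])
    return CohortTable(timepoint, df, specs, standardized=standardized)


@pytest.fixture
def make_std_table():
    return make_table


@pytest.fixture(scope="session")
def phenotype_recovery():
    """Default 4-phenotype cohort (n=800, no attrition) clustered end to end."""
    cfg = recovery_config("phenotype", n_total=800, seed=7)
    cohort = generate_cohort(cfg)
    t0_std, t1_std, counts, _ = preprocess(cohort.t0_raw, cohort.t1_raw)
    method = SilhouettePAM()
    from tinnpheno import cluster_baseline

    assignment = cluster_baseline(t0_std, method=method, seed=1)
    return {
        "cohort": cohort,
        "t0_std": t0_std,
        "t1_std": t1_std,
        "assignment": assignment,
        "method": method,
    }


@pytest.fixture(scope="session")
def pathway_recovery():
    """5-pathway cohort with 2-SD-plus shift gaps, clustered on change vectors."""
    from tinnpheno import cluster_deltas, order_and_label

    cfg = recovery_config("pathway", n_total=800, seed=7)
    cohort = generate_cohort(cfg)
    t0_std, t1_std, _, _ = preprocess(cohort.t0_raw, cohort.t1_raw)
    deltas = compute_deltas(t0_std, t1_std)
    method = SilhouettePAM()
    raw = cluster_deltas(deltas, method=method, seed=1)
    assignment = order_and_label(raw, deltas)
    return {
        "cohort": cohort,
        "t0_std": t0_std,
        "deltas": deltas,
        "assignment": assignment,
        "method": method,
    }
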