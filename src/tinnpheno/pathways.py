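"""Pathways of change: clustering per-patient change vectors and relating
them to baseline phenotypes.

The change vector of a patient is the element-wise standardized difference
``delta = t1 - t0``; negative values mean improvement. Change vectors are
clustered with the same pluggable backend as baseline phenotyping, and the
resulting pathways are ordered by decreasing mean overall change (so
pathway 1 is the strongest deterioration and the last pathway the strongest
improvement). With five pathways the canonical names
"high deterioration" ... "high improvement" are attached.

Association with baseline is quantified two ways: a Pearson chi-square test
of independence on the phenotype-by-pathway contingency table, and Spearman
correlations of every baseline variable with one-vs-rest pathway membership,
with percentile-bootstrap confidence intervals over patient resamples
(2000 resamples by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, check_aligned
from .errors import DataValidationError
from .phenotyping import SilhouettePAM, relabel_by_size

PATHWAY_NAMES_5 = (
    "high deterioration",
    "low deterioration",
    "low improvement",
    "moderate improvement",
    "high improvement",
)


def compute_deltas(t0_std: CohortTable, t1_std: CohortTable) -> pd.DataFrame:
    """Element-wise standardized change ``t1 - t0`` (negative = improvement)."""
    if not (t0_std.standardized and t1_std.standardized):
        raise DataValidationError("compute_deltas expects standardized tables")
    check_aligned(t0_std, t1_std)
    return t1_std.data - t0_std.data


def cluster_deltas(deltas: pd.DataFrame, method=None, seed: int = 0) -> np.ndarray:
    """Cluster change vectors; same plug-in interface and determinism as phenotyping."""
    if len(deltas) < 10:
        raise DataValidationError(f"need at least 10 patients, got {len(deltas)}")
    if method is None:
        method = SilhouettePAM()
    return np.asarray(method.fit(deltas.to_numpy(dtype=float), random_state=seed))


@dataclass
class PathwayAssignment:
    """Ordered pathway labels: 1 = most deterioration, m = most improvement."""

    labels: pd.Series  # patient id -> 1..m
    order_stat: pd.Series  # pathway -> mean overall delta, strictly used for ordering
    label_names: dict[int, str]
    m: int

    def __post_init__(self):
        present = set(self.labels.unique())
        if present != set(range(1, self.m + 1)):
            raise DataValidationError(
                f"pathway labels must cover 1..{self.m} (got {sorted(present)})"
            )

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def order_and_label(raw_labels: np.ndarray, deltas: pd.DataFrame) -> PathwayAssignment:
    """Rank clusters by decreasing mean overall change and attach names.

    The ordering statistic is the cluster mean of each patient's mean change
    across all variables. Ties keep the original cluster-index order. With
    five pathways the canonical names apply; otherwise "pathway r/m".
    """
    raw_labels = np.asarray(raw_labels)
    if len(raw_labels) != len(deltas):
        raise DataValidationError("labels are not aligned with the delta table")
    overall = deltas.mean(axis=1).to_numpy()
    uniq = np.unique(raw_labels)
    stat = np.array([overall[raw_labels == u].mean() for u in uniq])
    order = np.argsort(-stat, kind="stable")  # decreasing; ties by original index
    mapping = {uniq[o]: rank + 1 for rank, o in enumerate(order)}
    labels = pd.Series(
        [mapping[l] for l in raw_labels], index=deltas.index, name="pathway"
    )
    m = len(uniq)
    if m == 5:
        names = {r + 1: PATHWAY_NAMES_5[r] for r in range(5)}
    else:
        names = {r: f"pathway {r}/{m}" for r in range(1, m + 1)}
    order_stat = pd.Series(stat[order], index=range(1, m + 1), name="mean_overall_delta")
    order_stat.index.name = "pathway"
    return PathwayAssignment(labels=labels, order_stat=order_stat, label_names=names, m=m)


def pathway_profile(deltas: pd.DataFrame, assignment: PathwayAssignment) -> pd.DataFrame:
    """Within-pathway mean change per variable (pathways as rows)."""
    if not assignment.labels.index.equals(deltas.index):
        raise DataValidationError("assignment labels do not align with the delta table")
    prof = deltas.groupby(assignment.labels).mean()
    prof.index.name = "pathway"
    return prof


# -- Spearman correlations with percentile-bootstrap CIs -----------------------


def _rank(a: np.ndarray, axis: int) -> np.ndarray:
    return stats.rankdata(a, axis=axis)


def _pearson_along(a: np.ndarray, b: np.ndarray, axis: int) -> np.ndarray:
    a = a - a.mean(axis=axis, keepdims=True)
    b = b - b.mean(axis=axis, keepdims=True)
    num = (a * b).sum(axis=axis)
    den = np.sqrt((a**2).sum(axis=axis) * (b**2).sum(axis=axis))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation of two vectors."""
    return float(_pearson_along(_rank(x, 0), _rank(y, 0), axis=0))


def bootstrap_spearman_ci(
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 2000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Spearman correlation with a percentile-bootstrap CI over paired resamples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    r_boot = _pearson_along(_rank(x[idx], 1), _rank(y[idx], 1), axis=1)
    alpha = 1.0 - ci_level
    lo, hi = np.nanquantile(r_boot, [alpha / 2, 1 - alpha / 2])
    return spearman(x, y), float(lo), float(hi)


def spearman_with_pathways(
    t0_std: CohortTable,
    assignment: PathwayAssignment,
    n_boot: int = 2000,
    ci_level: float = 0.95,
    seed: int = 0,
    chunk: int = 200,
) -> pd.DataFrame:
    """Correlate every baseline variable with one-vs-rest pathway membership.

    Returns one row per (variable, pathway): the Spearman correlation between
    the baseline variable and the binary membership indicator, with a
    percentile-bootstrap CI over patient resamples (shared resamples across
    variables within a pathway). Pathways with fewer than 3 members get
    missing CIs.
    """
    if not assignment.labels.index.equals(t0_std.patient_ids):
        raise DataValidationError("assignment labels do not align with the table")
    X = t0_std.values()
    n, p = X.shape
    rx = _rank(X, 0)
    alpha = 1.0 - ci_level
    records = []
    for pathway in range(1, assignment.m + 1):
        y = (assignment.labels.to_numpy() == pathway).astype(float)
        est = _pearson_along(rx, _rank(y, 0)[:, None] * np.ones((1, p)), axis=0)
        if int(y.sum()) < 3:
            lo = hi = np.full(p, np.nan)
        else:
            rng = np.random.default_rng([seed, pathway])
            r_boot = np.empty((n_boot, p))
            done = 0
            while done < n_boot:
                b = min(chunk, n_boot - done)
                idx = rng.integers(0, n, size=(b, n))
                rxb = _rank(X[idx], 1)  # (b, n, p)
                ryb = _rank(y[idx], 1)[:, :, None]  # (b, n, 1)
                r_boot[done : done + b] = _pearson_along(rxb, ryb, axis=1)
                done += b
            lo, hi = np.nanquantile(r_boot, [alpha / 2, 1 - alpha / 2], axis=0)
        for j, var in enumerate(t0_std.variable_names):
            records.append(
                {
                    "variable": var,
                    "pathway": pathway,
                    "r": est[j],
                    "ci_lo": lo[j],
                    "ci_hi": hi[j],
                }
            )
    return pd.DataFrame(records)


# -- Phenotype/pathway association --------------------------------------------


@dataclass
class AssociationReport:
    """Chi-square independence test plus the baseline-variable Spearman panel."""

    chi2: float
    df: int
    p_value: float
    table: pd.DataFrame = field(repr=False)
    spearman: pd.DataFrame | None = field(repr=False, default=None)


def chi_square_association(
    phenotype_labels: pd.Series, pathway_labels: pd.Series
) -> AssociationReport:
    """Pearson chi-square of independence on the phenotype x pathway table."""
    if not phenotype_labels.index.equals(pathway_labels.index):
        raise DataValidationError("label vectors are not aligned")
    table = pd.crosstab(phenotype_labels, pathway_labels)
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise DataValidationError("contingency table has a zero marginal")
    chi2, p, df, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return AssociationReport(chi2=float(chi2), df=int(df), p_value=float(p), table=table)


def share(count: int, total: int) -> float:
    """Percentage of ``count`` in ``total``, one decimal, half away from zero."""
    if total <= 0:
        raise DataValidationError("share: total must be > 0")
    pct = 100.0 * count / total
    return math.copysign(math.floor(abs(pct) * 10 + 0.5) / 10, pct)


def mosaic_counts(
    phenotype_labels: pd.Series, pathway_labels: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Contingency counts plus within-phenotype percentages (one decimal)."""
    if not phenotype_labels.index.equals(pathway_labels.index):
        raise DataValidationError("label vectors are not aligned")
    counts = pd.crosstab(phenotype_labels, pathway_labels)
    if counts.to_numpy().sum() == 0:
        raise DataValidationError("mosaic_counts: empty labels")
    pct = counts.apply(
        lambda row: pd.Series(
            [share(c, row.sum()) for c in row], index=row.index
        ),
        axis=1,
    )
    return counts, pct
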