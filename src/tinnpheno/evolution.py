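"""Phenotype geometry through treatment: medoids, core hulls, transitions.

A phenotype's *core* is the half of its members closest to the medoid
(2-D distance to the medoid no greater than the median of all members'
medoid distances); the *core hull* is the convex hull of those members in
the projected plane — a growing core-hull area signals heterogeneous
treatment response within the phenotype. Post-treatment patients are
re-assigned to the phenotype of the Euclidean-nearest baseline medoid in
the full standardized space, which yields the transition table underlying
the Sankey view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull as _SciPyHull
from scipy.spatial import QhullError
from scipy.spatial.distance import cdist

from .cohort import CohortTable, check_aligned
from .errors import DataValidationError
from .phenotyping import PhenotypeAssignment, compute_medoid

#: Links whose patient share is at or below this fraction are hidden by default.
DEFAULT_MIN_LINK_SHARE = 0.03

#: Standardized mean-change threshold for flagging a variable improved/worsened.
FLAG_THRESHOLD = 0.25


def core_members(coords_2d: pd.DataFrame, member_ids, medoid_id) -> list:
    """Members whose 2-D distance to the medoid is <= the median member distance.

    The medoid itself contributes distance 0; for even member counts the
    median is the midpoint of the two middle distances, so exactly the
    nearest half (or slightly more, under ties) is retained.
    """
    member_ids = list(member_ids)
    if not member_ids:
        raise DataValidationError("core_members: empty membership")
    if medoid_id not in member_ids:
        raise DataValidationError(f"medoid {medoid_id!r} is not among the members")
    pts = coords_2d.loc[member_ids, ["x", "y"]].to_numpy(dtype=float)
    center = coords_2d.loc[medoid_id, ["x", "y"]].to_numpy(dtype=float)
    dist = np.linalg.norm(pts - center, axis=1)
    med = float(np.median(dist))
    return [m for m, d in zip(member_ids, dist) if d <= med + 1e-12]


def convex_hull(points_2d: np.ndarray) -> tuple[np.ndarray, float]:
    """Convex polygon (counterclockwise vertices) and shoelace area of a point set.

    Degenerate inputs (single point, collinear set) yield the extreme points
    and area 0.
    """
    pts = np.asarray(points_2d, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise DataValidationError("convex_hull: no points")
    uniq = np.unique(pts, axis=0)
    if len(uniq) < 3:
        return uniq, 0.0
    try:
        hull = _SciPyHull(uniq)
    except QhullError:  # collinear
        order = np.lexsort((uniq[:, 1], uniq[:, 0]))
        return uniq[[order[0], order[-1]]], 0.0
    verts = uniq[hull.vertices]  # scipy returns 2-D hull vertices counterclockwise
    x, y = verts[:, 0], verts[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))
    return verts, float(area)


@dataclass
class CoreHull:
    """Core membership and its convex polygon for one phenotype at one timepoint."""

    phenotype: int
    timepoint: str
    medoid_id: object
    member_ids: list = field(repr=False)
    vertices: np.ndarray = field(repr=False)
    area: float = 0.0


def build_core_hull(
    phenotype: int,
    timepoint: str,
    coords_2d: pd.DataFrame,
    member_ids,
    medoid_id,
) -> CoreHull:
    core = core_members(coords_2d, member_ids, medoid_id)
    verts, area = convex_hull(coords_2d.loc[core, ["x", "y"]].to_numpy(dtype=float))
    return CoreHull(phenotype, timepoint, medoid_id, core, verts, area)


def assign_t1(t1_std: CohortTable, medoid_vectors: pd.DataFrame) -> pd.Series:
    """Label each t1 patient with the cluster of the nearest baseline medoid.

    ``medoid_vectors`` is indexed by cluster (1..k) over the standardized
    variable space. Ties break toward the lowest cluster index.
    """
    if list(medoid_vectors.columns) != t1_std.variable_names:
        raise DataValidationError("medoid vectors do not match the table variables")
    clusters = medoid_vectors.index.to_numpy()
    order = np.argsort(clusters)
    D = cdist(t1_std.values(), medoid_vectors.to_numpy(dtype=float)[order])
    nearest = clusters[order][np.argmin(D, axis=1)]  # argmin takes first -> lowest index
    return pd.Series(nearest, index=t1_std.patient_ids, name="phenotype_t1")


@dataclass
class TransitionTable:
    """k x k patient counts: rows = baseline phenotype, columns = t1 assignment."""

    counts: pd.DataFrame
    link_shares: pd.DataFrame

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())


def transition_table(t0_labels: pd.Series, t1_labels: pd.Series) -> TransitionTable:
    if not t0_labels.index.equals(t1_labels.index):
        raise DataValidationError("label vectors are not aligned")
    clusters = sorted(set(t0_labels.unique()) | set(t1_labels.unique()))
    counts = (
        pd.crosstab(t0_labels, t1_labels)
        .reindex(index=clusters, columns=clusters, fill_value=0)
        .astype(int)
    )
    counts.index.name, counts.columns.name = "from", "to"
    return TransitionTable(counts=counts, link_shares=counts / len(t0_labels))


def sankey_links(
    table: TransitionTable, min_share: float = DEFAULT_MIN_LINK_SHARE
) -> pd.DataFrame:
    """Flatten the transition table to links, hiding shares <= ``min_share``.

    Counts are untouched — only the link list is filtered for display.
    """
    rows = []
    n = table.n
    for a in table.counts.index:
        for b in table.counts.columns:
            c = int(table.counts.at[a, b])
            share = c / n
            if c > 0 and share > min_share:
                rows.append({"from": a, "to": b, "count": c, "share": share})
    return pd.DataFrame(rows, columns=["from", "to", "count", "share"])


def radial_summary(
    t0_std: CohortTable, t1_std: CohortTable, labels: pd.Series
) -> pd.DataFrame:
    """Per-phenotype, per-variable change summary behind the radial bar graphs.

    For each phenotype and variable: the standardized means at both
    timepoints, the phenotype's mean change relative to the population mean
    change, and a flag — ``improved`` when the t0 mean exceeds the t1 mean by
    more than 0.25, ``worsened`` for the reverse, ``none`` otherwise.
    """
    check_aligned(t0_std, t1_std)
    if not labels.index.equals(t0_std.patient_ids):
        raise DataValidationError("labels are not aligned with the tables")
    pop_change = (t1_std.data - t0_std.data).mean()
    records = []
    for pheno, ids in labels.groupby(labels).groups.items():
        m0 = t0_std.data.loc[ids].mean()
        m1 = t1_std.data.loc[ids].mean()
        change = m1 - m0
        for var in t0_std.variable_names:
            d = change[var]
            flag = "improved" if -d > FLAG_THRESHOLD else ("worsened" if d > FLAG_THRESHOLD else "none")
            records.append(
                {
                    "phenotype": pheno,
                    "variable": var,
                    "mean_t0": m0[var],
                    "mean_t1": m1[var],
                    "delta_vs_population": d - pop_change[var],
                    "flag": flag,
                }
            )
    return pd.DataFrame(records)


@dataclass
class EvolutionResult:
    """Everything the change-with-treatment stage produces."""

    t1_labels: pd.Series
    transitions: TransitionTable
    hulls_t0: dict[int, CoreHull]
    hulls_t1: dict[int, CoreHull]
    medoids_t1: dict[int, object]
    summary: pd.DataFrame


def evolve(
    t0_std: CohortTable,
    t1_std: CohortTable,
    assignment: PhenotypeAssignment,
    coords_t0: pd.DataFrame,
    coords_t1: pd.DataFrame,
) -> EvolutionResult:
    """Run the full change-modeling stage.

    Baseline core hulls use the t0 coordinates, members and medoids. The t1
    phenotype of every patient is the nearest baseline medoid in the full
    standardized space; t1 core hulls are built over those reassigned
    members, around a medoid recomputed at t1.
    """
    check_aligned(t0_std, t1_std)
    medoid_vectors = pd.DataFrame(
        {c: t0_std.data.loc[mid] for c, mid in assignment.medoid_ids.items()}
    ).T
    medoid_vectors.index.name = "phenotype"
    t1_labels = assign_t1(t1_std, medoid_vectors)

    hulls_t0 = {
        c: build_core_hull(c, "t0", coords_t0, assignment.members(c), assignment.medoid_ids[c])
        for c in range(1, assignment.k + 1)
    }
    hulls_t1, medoids_t1 = {}, {}
    for c in range(1, assignment.k + 1):
        members = t1_labels.index[t1_labels == c]
        if len(members) == 0:
            continue
        med = compute_medoid(t1_std.data, members)
        medoids_t1[c] = med
        hulls_t1[c] = build_core_hull(c, "t1", coords_t1, members, med)

    return EvolutionResult(
        t1_labels=t1_labels,
        transitions=transition_table(assignment.labels, t1_labels),
        hulls_t0=hulls_t0,
        hulls_t1=hulls_t1,
        medoids_t1=medoids_t1,
        summary=radial_summary(t0_std, t1_std, assignment.labels),
    )
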