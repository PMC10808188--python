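"""Baseline phenotyping: k-medoids clustering with silhouette-based model selection.

The clustering backend is pluggable: any object with a
``fit(X, random_state) -> labels`` method (0-based integer labels) can stand
in. The default, :class:`SilhouettePAM`, partitions around medoids for every
candidate k and keeps the k with maximal mean silhouette width, which both
selects the number of subgroups automatically and yields medoid-centric
clusters matching the downstream geometry.

Clusters are relabeled 1..k in decreasing size order, so phenotype 1 is
always the largest subgroup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.metrics import silhouette_score

from .cohort import CohortTable
from .errors import ConfigurationError, DataValidationError


class KMedoids:
    """Alternating (Voronoi-iteration) k-medoids with k-medoids++ seeding.

    Works on a precomputed Euclidean distance matrix; restarts ``n_init``
    times from different seeded initializations and keeps the lowest-cost
    solution (cost = sum of distances of every point to its medoid).
    """

    def __init__(self, n_clusters: int, n_init: int = 10, max_iter: int = 200):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.medoid_indices_: np.ndarray | None = None
        self.labels_: np.ndarray | None = None
        self.cost_: float = np.inf

    @staticmethod
    def _init_medoids(D: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
        """k-medoids++ : first medoid uniform, the rest distance-squared weighted."""
        n = D.shape[0]
        medoids = [int(rng.integers(n))]
        for _ in range(1, k):
            d2 = np.min(D[:, medoids], axis=1) ** 2
            total = d2.sum()
            if total <= 0:  # fewer distinct points than k; fall back to uniform
                candidates = np.setdiff1d(np.arange(n), medoids)
                medoids.append(int(rng.choice(candidates)))
                continue
            medoids.append(int(rng.choice(n, p=d2 / total)))
        return np.array(medoids)

    def fit_distances(self, D: np.ndarray, random_state: int = 0) -> "KMedoids":
        n = D.shape[0]
        if self.n_clusters > n:
            raise ConfigurationError(
                f"n_clusters={self.n_clusters} exceeds number of points ({n})"
            )
        best_cost, best_medoids, best_labels = np.inf, None, None
        for init in range(self.n_init):
            rng = np.random.default_rng([random_state, init])
            medoids = self._init_medoids(D, self.n_clusters, rng)
            for _ in range(self.max_iter):
                labels = np.argmin(D[:, medoids], axis=1)
                new_medoids = medoids.copy()
                for c in range(self.n_clusters):
                    members = np.flatnonzero(labels == c)
                    if len(members) == 0:
                        continue
                    within = D[np.ix_(members, members)].sum(axis=1)
                    new_medoids[c] = members[int(np.argmin(within))]
                if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
                    break
                medoids = new_medoids
            labels = np.argmin(D[:, medoids], axis=1)
            cost = D[np.arange(n), medoids[labels]].sum()
            if cost < best_cost - 1e-12:
                best_cost, best_medoids, best_labels = cost, medoids, labels
        self.cost_ = float(best_cost)
        self.medoid_indices_ = best_medoids
        self.labels_ = best_labels
        return self

    def fit(self, X: np.ndarray, random_state: int = 0) -> np.ndarray:
        D = squareform(pdist(np.asarray(X, dtype=float)))
        self.fit_distances(D, random_state=random_state)
        return self.labels_


@dataclass
class SilhouettePAM:
    """Default clustering plug-in: PAM for each k, pick k by maximal mean silhouette.

    Ties on silhouette go to the smaller k. After fitting, ``k_`` holds the
    selected number of clusters and ``silhouettes_`` the per-k mean widths.
    """

    k_range: tuple[int, int] = (2, 10)
    n_init: int = 10
    k_: int | None = None
    silhouettes_: dict[int, float] = field(default_factory=dict)

    def fit(self, X: np.ndarray, random_state: int = 0) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        lo, hi = self.k_range
        if not 2 <= lo <= hi:
            raise ConfigurationError(f"k_range: need 2 <= lo <= hi, got {self.k_range}")
        hi = min(hi, n - 1)
        if lo > hi:
            raise ConfigurationError(f"k_range lower bound {lo} too large for n={n}")
        D = squareform(pdist(X))
        best = None  # (silhouette, -k) maximized
        self.silhouettes_ = {}
        for k in range(lo, hi + 1):
            km = KMedoids(k, n_init=self.n_init).fit_distances(D, random_state=random_state)
            labels = km.labels_
            if len(np.unique(labels)) < 2:
                continue
            sil = float(silhouette_score(D, labels, metric="precomputed"))
            self.silhouettes_[k] = sil
            if best is None or sil > best[0] + 1e-12:
                best = (sil, k, labels)
        if best is None:
            raise DataValidationError("silhouette selection failed for every k")
        self.k_ = best[1]
        return best[2]


@dataclass
class PhenotypeAssignment:
    """Cluster labels (1..k, size-ranked), one medoid patient id per cluster."""

    labels: pd.Series  # patient id -> 1..k
    medoid_ids: dict[int, object]
    k: int
    method_tag: str

    def __post_init__(self):
        present = set(self.labels.unique())
        if present != set(range(1, self.k + 1)):
            raise DataValidationError(
                f"labels must cover 1..{self.k} with no empty cluster (got {sorted(present)})"
            )
        for c, mid in self.medoid_ids.items():
            if self.labels.get(mid) != c:
                raise DataValidationError(
                    f"medoid {mid!r} of cluster {c} does not belong to that cluster"
                )

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def members(self, cluster: int) -> pd.Index:
        return self.labels.index[self.labels == cluster]


def compute_medoid(points: pd.DataFrame, member_ids) -> object:
    """The member minimizing the summed Euclidean distance to all members.

    Ties break toward the lowest patient id.
    """
    member_ids = list(member_ids)
    if len(member_ids) == 0:
        raise DataValidationError("compute_medoid: empty member set")
    X = points.loc[member_ids].to_numpy(dtype=float)
    D = cdist(X, X)
    totals = D.sum(axis=1)
    best = totals.min()
    tied = [member_ids[i] for i in np.flatnonzero(totals <= best + 1e-12)]
    return min(tied)


def relabel_by_size(raw_labels: np.ndarray) -> np.ndarray:
    """Map 0-based cluster labels to 1..k in decreasing size (ties: lower old label)."""
    uniq, counts = np.unique(raw_labels, return_counts=True)
    order = sorted(range(len(uniq)), key=lambda i: (-counts[i], uniq[i]))
    mapping = {uniq[o]: rank + 1 for rank, o in enumerate(order)}
    return np.array([mapping[l] for l in raw_labels])


def cluster_baseline(
    t0_std: CohortTable,
    method=None,
    seed: int = 0,
) -> PhenotypeAssignment:
    """Cluster the standardized baseline table into phenotypes.

    Deterministic given the seed. Clusters are relabeled largest-first and
    each cluster's medoid is computed in the full standardized variable space.
    """
    if not t0_std.standardized:
        raise DataValidationError("cluster_baseline expects a standardized table")
    if t0_std.n_patients < 10:
        raise DataValidationError(
            f"need at least 10 patients to phenotype, got {t0_std.n_patients}"
        )
    if method is None:
        method = SilhouettePAM()
    raw = np.asarray(method.fit(t0_std.values(), random_state=seed))
    labels = pd.Series(relabel_by_size(raw), index=t0_std.patient_ids, name="phenotype")
    k = int(labels.max())
    medoids = {
        c: compute_medoid(t0_std.data, labels.index[labels == c]) for c in range(1, k + 1)
    }
    tag = f"{type(method).__name__}(k={k}, seed={seed})"
    return PhenotypeAssignment(labels=labels, medoid_ids=medoids, k=k, method_tag=tag)


def phenotype_profile(assignment: PhenotypeAssignment, t_std: CohortTable) -> pd.DataFrame:
    """Per-cluster mean of every standardized variable (clusters as rows)."""
    if not assignment.labels.index.equals(t_std.patient_ids):
        raise DataValidationError("assignment labels do not align with the table")
    prof = t_std.data.groupby(assignment.labels).mean()
    prof.index.name = "phenotype"
    return prof
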