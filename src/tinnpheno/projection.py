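"""2-D embedding of patients and the factor map relating variables to the plane.

The default engine is UMAP (nonlinear, seed-fixed, supports out-of-sample
transform of the post-treatment table into the baseline-fitted map); a PCA
engine is provided as a fully deterministic linear fallback whose transform
of a training point reproduces its training coordinate exactly.

The factor map assigns each original variable the pair of Pearson
correlations with the two projected dimensions, drawn as an arrow whose
angle follows the correlation signs and whose length is the correlation
strength. Rings summarize strength: outer for magnitude >= 0.75, inner for
<= 0.5, middle otherwise (both boundaries closed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .cohort import CohortTable
from .errors import ConfigurationError, DataValidationError

ENGINES = ("umap", "pca")

RING_OUTER = 0.75
RING_INNER = 0.50


@dataclass
class EmbeddingModel:
    """A fitted 2-D embedding with out-of-sample projection support."""

    engine: str
    seed: int
    variable_names: list[str] = field(repr=False)
    training_ids: pd.Index = field(repr=False)
    training_coords: pd.DataFrame = field(repr=False)  # columns x, y
    _fitted: object = field(repr=False, default=None)


def fit_embedding(t0_std: CohortTable, engine: str = "umap", seed: int = 0) -> EmbeddingModel:
    """Fit the 2-D embedding on the standardized baseline table."""
    if engine not in ENGINES:
        raise ConfigurationError(f"engine must be one of {ENGINES}, got {engine!r}")
    if not t0_std.standardized:
        raise DataValidationError("fit_embedding expects a standardized table")
    X = t0_std.values()
    if engine == "pca":
        model = PCA(n_components=2, svd_solver="full", random_state=seed)
        coords = model.fit_transform(X)
    else:
        import umap  # deferred: numba JIT import is slow

        model = umap.UMAP(n_components=2, random_state=seed, n_jobs=1)
        coords = model.fit_transform(X)
    frame = pd.DataFrame(
        np.asarray(coords, dtype=float), index=t0_std.patient_ids, columns=["x", "y"]
    )
    return EmbeddingModel(
        engine=engine,
        seed=seed,
        variable_names=t0_std.variable_names,
        training_ids=t0_std.patient_ids,
        training_coords=frame,
        _fitted=model,
    )


def project(model: EmbeddingModel, table: CohortTable) -> pd.DataFrame:
    """Out-of-sample projection of a standardized table into the fitted plane."""
    if table.variable_names != model.variable_names:
        raise DataValidationError("table variables do not match the fitted embedding")
    coords = model._fitted.transform(table.values())
    return pd.DataFrame(
        np.asarray(coords, dtype=float), index=table.patient_ids, columns=["x", "y"]
    )


def classify_ring(magnitude: float) -> str:
    """Ring class for a correlation-vector magnitude (closed 0.75 / 0.5 boundaries)."""
    if magnitude >= RING_OUTER:
        return "outer"
    if magnitude <= RING_INNER:
        return "inner"
    return "middle"


def compute_factor_map(t_std: CohortTable, coords: pd.DataFrame) -> pd.DataFrame:
    """Correlate every original variable with the two projected dimensions.

    Returns one row per variable: ``r1``/``r2`` (Pearson correlation with the
    x and y dimension), ``magnitude`` (Euclidean norm of the pair) and
    ``ring``. Arrow orientation follows the signs: a negative ``r2`` points
    downward.
    """
    if not coords.index.equals(t_std.patient_ids):
        raise DataValidationError("coordinates are not aligned with the table rows")
    C = coords[["x", "y"]].to_numpy(dtype=float)
    sd = C.std(axis=0, ddof=1)
    if not (sd > 0).all():
        dim = "x" if sd[0] <= 0 else "y"
        raise DataValidationError(f"projected dimension {dim!r} has zero variance")
    Cc = (C - C.mean(axis=0)) / sd
    X = t_std.values()
    x_sd = X.std(axis=0, ddof=1)
    if not (x_sd > 0).all():
        bad = t_std.variable_names[int(np.flatnonzero(~(x_sd > 0))[0])]
        raise DataValidationError(f"variable {bad!r} has zero variance")
    Xc = (X - X.mean(axis=0)) / x_sd
    n = X.shape[0]
    r = Xc.T @ Cc / (n - 1)  # variables x 2 Pearson correlations
    magnitude = np.linalg.norm(r, axis=1)
    return pd.DataFrame(
        {
            "variable": t_std.variable_names,
            "r1": r[:, 0],
            "r2": r[:, 1],
            "magnitude": magnitude,
            "ring": [classify_ring(m) for m in magnitude],
        }
    )
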