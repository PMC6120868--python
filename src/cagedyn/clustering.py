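"""k-means clustering of time-course profiles.

Expression profiles (typically log2FC versus baseline of TF promoters) and
motif-activity profiles are clustered with Euclidean k-means (Lloyd's
algorithm, k-means++ seeding, best of `n_restarts` by inertia) into a fixed
number of clusters -- 10 for promoter expression, 5 for motif activities by
default.  Cluster indices are relabelled by the peak time of the centroid so
reports are stable and readable; labels are otherwise arbitrary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io import PromoterAnnotation, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterResult",
    "profile_matrix",
    "kmeans_profiles",
    "mean_cluster_profiles",
    "select_tf_promoters",
]


@dataclass(frozen=True)
class ClusterResult:
    """Assignments (1..k), centroids (k x T), inertia and the RNG settings."""

    item_ids: tuple
    k: int
    assignments: pd.Series  # item_id -> cluster index in 1..k
    centroids: pd.DataFrame  # index 1..k, columns = time points
    inertia: float
    seed: int
    n_restarts: int


def profile_matrix(matrix: pd.DataFrame, transform: str = "none") -> pd.DataFrame:
    """Row-wise transform of an items x time matrix.

    transform: 'none' (identity), 'zscore' (per-row standardization;
    zero-variance rows map to zeros, logged), or 'log2fc_vs_t0'
    (log2((x_t+1)/(x_0+1)) against the t=0 column, which must be present).
    """
    if transform == "none":
        return matrix.copy()
    if transform == "zscore":
        arr = matrix.to_numpy(dtype=float)
        mu = arr.mean(axis=1, keepdims=True)
        sd = arr.std(axis=1, keepdims=True)
        flat = (sd == 0).ravel()
        if flat.any():
            logger.warning("profile_matrix: %d zero-variance rows mapped to zeros", int(flat.sum()))
        sd[sd == 0] = 1.0
        out = (arr - mu) / sd
        out[flat, :] = 0.0
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    if transform == "log2fc_vs_t0":
        if 0 not in matrix.columns:
            raise ValidationError("log2fc_vs_t0 transform needs a t=0 column")
        base = matrix[0] + 1.0
        times = [t for t in matrix.columns if t != 0]
        return pd.DataFrame(
            {t: np.log2((matrix[t] + 1.0) / base) for t in times}, index=matrix.index
        )
    raise ValidationError(f"unknown transform {transform!r}")


def kmeans_profiles(
    matrix: pd.DataFrame,
    k: int,
    seed: int,
    n_restarts: int = 25,
) -> ClusterResult:
    """Euclidean k-means on profile rows; deterministic given (seed, n_restarts)."""
    if k > matrix.shape[0]:
        raise ValidationError(f"k={k} exceeds the number of items ({matrix.shape[0]})")
    if k < 1:
        raise ValidationError("k must be >= 1")
    X = matrix.to_numpy(dtype=float)
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_restarts,
        algorithm="lloyd",
        random_state=seed,
    ).fit(X)
    # relabel clusters by centroid peak time (then by centroid norm) for stable reports
    peaks = km.cluster_centers_.argmax(axis=1)
    order = np.lexsort((-np.abs(km.cluster_centers_).max(axis=1), peaks))
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    assignments = pd.Series(relabel[km.labels_], index=matrix.index, name="cluster")
    centroids = pd.DataFrame(
        km.cluster_centers_[order], index=np.arange(1, k + 1), columns=matrix.columns
    )
    return ClusterResult(
        item_ids=tuple(matrix.index),
        k=k,
        assignments=assignments,
        centroids=centroids,
        inertia=float(km.inertia_),
        seed=seed,
        n_restarts=n_restarts,
    )


def mean_cluster_profiles(
    result: ClusterResult, matrix: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-cluster arithmetic mean profile and member counts."""
    if not result.assignments.index.equals(matrix.index):
        raise ValidationError("assignments do not cover the matrix rows")
    grouped = matrix.groupby(result.assignments)
    means = grouped.mean()
    sizes = grouped.size().rename("n_members")
    return means, sizes


def select_tf_promoters(annotations: list[PromoterAnnotation]) -> set[str]:
    """Promoter ids flagged as transcription-factor genes."""
    ids = {a.promoter_id for a in annotations if a.is_tf}
    if not ids:
        logger.warning("select_tf_promoters: no promoters flagged as TFs")
    return ids
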