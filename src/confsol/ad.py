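"""k-nearest-neighbour applicability domain (AD) on scaled descriptors.

The AD is defined entirely by the training set.  Each training sample gets
a distance threshold derived from the distribution of mean k-nearest-
neighbour distances; a query compound is inside the AD if its Euclidean
distance to *at least one* training sample does not exceed that sample's
threshold.  Distances are Euclidean on descriptors scaled by the training
preprocessor, so the AD must always see matrices transformed by the same
:class:`~confsol.data.PreprocessModel`.

The per-sample threshold rule lives in :func:`knn_thresholds` so it can be
swapped without touching the decision logic: threshold_i is the mean
distance from sample i to its k nearest training neighbours, capped
globally at ``RefVal = Q3 + 1.5·IQR`` of those mean-kNN distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from .errors import DegenerateInputError, ParameterError, SchemaError


@dataclass
class ADModel:
    """Fitted kNN applicability domain.

    Attributes
    ----------
    Z_train : ndarray
        Scaled training matrix the domain was fitted on.
    k_neighbors : int
        Number of neighbours used for the mean-kNN distances.
    thresholds : ndarray
        Per-training-sample distance thresholds (Euclidean units).
    """

    Z_train: np.ndarray
    k_neighbors: int
    thresholds: np.ndarray


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def knn_thresholds(Z_train: np.ndarray, k: int) -> np.ndarray:
    """Per-sample thresholds from the mean-kNN-distance distribution.

    threshold_i = min(mean distance of i to its k nearest neighbours,
    RefVal) with RefVal = Q3 + 1.5·IQR over all mean-kNN distances.
    Neighbour ties are broken by row order (stable sort), so the result is
    deterministic.
    """
    D = cdist(Z_train, Z_train)
    np.fill_diagonal(D, np.inf)
    # stable partial sort: k smallest distances per row, ties by row order
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    knn_mean = np.take_along_axis(D, order, axis=1).mean(axis=1)
    q1, q3 = np.percentile(knn_mean, [25, 75])
    ref_val = q3 + 1.5 * (q3 - q1)
    return np.minimum(knn_mean, ref_val)


def fit_ad(Z_train: np.ndarray, k_fraction: float = 0.375) -> ADModel:
    """Fit the applicability domain on a scaled training matrix.

    ``k_neighbors = round(k_fraction · n_train)`` (round half up, floored
    at 1).  The default fraction 0.375 minimised outside-AD counts on large
    aqueous-solubility training sets; 0.05 is the stricter variant used for
    curated sets.
    """
    Z_train = np.asarray(Z_train, dtype=float)
    if Z_train.ndim != 2 or len(Z_train) < 3:
        raise DegenerateInputError("need a 2-D matrix with ≥3 training rows")
    if not 0.0 < k_fraction < 1.0:
        raise ParameterError(f"k_fraction must be in (0,1), got {k_fraction}")
    k = max(1, _round_half_up(k_fraction * len(Z_train)))
    k = min(k, len(Z_train) - 1)
    return ADModel(
        Z_train=Z_train, k_neighbors=k, thresholds=knn_thresholds(Z_train, k)
    )


def check_ad(model: ADModel, Z_query: np.ndarray) -> np.ndarray:
    """Boolean vector: True where the query compound is inside the AD.

    Inside ⇔ distance to at least one training sample i is ≤ thresholds[i]
    (boundary counts as inside).
    """
    Z_query = np.atleast_2d(np.asarray(Z_query, dtype=float))
    if Z_query.shape[1] != model.Z_train.shape[1]:
        raise SchemaError(
            f"query has {Z_query.shape[1]} columns, AD was fitted on "
            f"{model.Z_train.shape[1]}"
        )
    D = cdist(Z_query, model.Z_train)
    return (D <= model.thresholds[np.newaxis, :]).any(axis=1)


def min_scaled_distance(model: ADModel, Z_query: np.ndarray) -> np.ndarray:
    """Minimum Euclidean distance of each query to the training set (diagnostic)."""
    Z_query = np.atleast_2d(np.asarray(Z_query, dtype=float))
    return cdist(Z_query, model.Z_train).min(axis=1)


def ad_coverage(model: ADModel, Z_query: np.ndarray) -> float:
    """Percentage of query compounds *outside* the AD."""
    Z_query = np.atleast_2d(np.asarray(Z_query, dtype=float))
    if len(Z_query) == 0:
        raise DegenerateInputError("empty query set")
    inside = check_ad(model, Z_query)
    return 100.0 * float((~inside).sum()) / len(inside)


def pca_projection(
    Z_train: np.ndarray, Z_query: np.ndarray, n_components: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Project training and query matrices onto training-fitted PCA axes.

    Diagnostics only (descriptor-space coverage plots); the AD decision
    never uses these coordinates.
    """
    Z_train = np.asarray(Z_train, dtype=float)
    Z_query = np.atleast_2d(np.asarray(Z_query, dtype=float))
    max_rank = min(Z_train.shape)
    if not 1 <= n_components <= max_rank:
        raise ParameterError(
            f"n_components must be in 1..{max_rank}, got {n_components}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores_train = pca.fit_transform(Z_train)
    scores_query = pca.transform(Z_query)
    return scores_train, scores_query
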