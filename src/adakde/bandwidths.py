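"""Per-point bandwidth assignment by k-nearest-neighbor rules.

KNN1 sets each point's bandwidth to the distance to its k-th nearest
neighbor (among the other points, duplicates contributing zero distances).
KNN2 keeps the KNN1 value unless all k nearest neighbors lie strictly on
one side of the point, in which case the bandwidth becomes the distance to
the nearest point on the opposite side; this guarantees that consecutive
data points always have at least one kernel spanning the gap between them,
so the resulting density is positive everywhere between the extreme points.
"""

from __future__ import annotations

import numpy as np

__all__ = ["knn1_bandwidths", "knn2_bandwidths", "H_MIN_BANDWIDTH"]

#: duplicate positions can make the k-th NN distance 0; a kernel needs width
H_MIN_BANDWIDTH = 1.0


def _as_sorted_positions(X) -> np.ndarray:
    x = np.asarray(getattr(X, "positions", X), dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("positions must be one-dimensional")
    if x.size == 0:
        raise ValueError("positions must be non-empty")
    if np.any(np.diff(x) < 0):
        raise ValueError("positions must be sorted ascending")
    return x


def _neighbor_distances(x: np.ndarray, k: int) -> np.ndarray:
    """(n, 2k) array of distances to the k adjacent points on each side.

    Column layout: [left_1..left_k, right_1..right_k], padded with +inf
    where fewer than k neighbors exist on that side.  Because ``x`` is
    sorted, the k-th nearest neighbor of any point is among these 2k
    candidates.
    """
    n = x.size
    d = np.full((n, 2 * k), np.inf)
    for j in range(1, k + 1):
        d[j:, j - 1] = x[j:] - x[:-j]          # j-th left neighbor
        d[:-j, k + j - 1] = x[j:] - x[:-j]     # j-th right neighbor
    return d


def knn1_bandwidths(X, k: int, h_min: float = H_MIN_BANDWIDTH) -> np.ndarray:
    """Distance from each point to its k-th nearest neighbor, floored at ``h_min``.

    Distances form a multiset over the other points, so m duplicates of a
    position contribute m zero distances.
    """
    x = _as_sorted_positions(X)
    n = x.size
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k >= n:
        raise ValueError(f"k must be < n ({n}), got {k}")
    d = _neighbor_distances(x, k)
    kth = np.partition(d, k - 1, axis=1)[:, k - 1]
    return np.maximum(kth, h_min)


def knn2_bandwidths(X, k: int, h_min: float = H_MIN_BANDWIDTH) -> np.ndarray:
    """KNN1 bandwidths with the opposite-side override.

    A point whose k nearest neighbors all lie strictly on one side takes
    instead the distance to its nearest point on the other side.  Points at
    the extremes of the range with no opposite-side point keep their KNN1
    value.  A tie in distance at rank k between a left and a right neighbor
    counts as mixed-side (no override).
    """
    x = _as_sorted_positions(X)
    n = x.size
    h = knn1_bandwidths(x, k, h_min=h_min)

    idx = np.arange(n)
    # distance to the k-th same-side neighbor (inf when fewer than k exist)
    left_k = np.where(idx >= k, x - x[np.maximum(idx - k, 0)], np.inf)
    right_k = np.where(idx < n - k, x[np.minimum(idx + k, n - 1)] - x, np.inf)
    # distance to the single nearest opposite-side point
    left_1 = np.where(idx >= 1, x - x[np.maximum(idx - 1, 0)], np.inf)
    right_1 = np.where(idx < n - 1, x[np.minimum(idx + 1, n - 1)] - x, np.inf)

    # all k nearest strictly on the left: k-th left distance beats the
    # nearest right distance (strict comparison makes exact ties mixed-side)
    all_left = left_k < right_1
    all_right = right_k < left_1
    override_left = all_left & np.isfinite(right_1)
    override_right = all_right & np.isfinite(left_1)
    h = np.where(override_left, np.maximum(right_1, h_min), h)
    h = np.where(override_right, np.maximum(left_1, h_min), h)
    return h


def bandwidths_for_rule(X, rule: str, k: int,
                        h_min: float = H_MIN_BANDWIDTH) -> np.ndarray:
    if rule == "knn1":
        return knn1_bandwidths(X, k, h_min=h_min)
    if rule == "knn2":
        return knn2_bandwidths(X, k, h_min=h_min)
    raise ValueError(f"unknown bandwidth rule {rule!r}; expected 'knn1' or 'knn2'")
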