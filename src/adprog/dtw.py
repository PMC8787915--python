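"""Dynamic time warping distances for short cognitive-score series.

Classic unconstrained DTW with absolute-difference local cost and the
symmetric step pattern {(1,0), (0,1), (1,1)} — a global alignment with no
warping window and no path-length normalization.  For the 4-visit series
this package targets, the dynamic program is tiny; :func:`pairwise_dtw`
vectorizes the DP across all subject pairs so cohort-scale distance
matrices stay fast in pure NumPy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DistanceMatrix", "dtw_distance", "pairwise_dtw"]


class MissingDataError(ValueError):
    """Raised when a sequence contains NaN (no imputation at this layer)."""


@dataclass
class DistanceMatrix:
    """Symmetric subject x subject dissimilarity matrix."""

    values: np.ndarray
    metric_name: str = "dtw"
    subject_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("distance matrix must be finite")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diagonal(v) != 0):
            raise ValueError("distance matrix must have zero diagonal")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


def dtw_distance(a, b, local_cost: str = "abs") -> float:
    """DTW distance between two sequences.

    Parameters
    ----------
    a, b
        Non-empty 1-D sequences of finite scores.
    local_cost
        ``"abs"`` (|a_i - b_j|, default) or ``"sq"`` (squared difference).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("DTW requires non-empty sequences")
    if np.any(np.isnan(a)) or np.any(np.isnan(b)):
        raise MissingDataError("sequence contains NaN; drop or complete the series first")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("sequences must be finite")

    cost = np.abs(a[:, None] - b[None, :])
    if local_cost == "sq":
        cost = cost**2
    elif local_cost != "abs":
        raise ValueError(f"unknown local cost {local_cost!r}")

    n, m = cost.shape
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            acc[i, j] = cost[i - 1, j - 1] + min(acc[i - 1, j], acc[i, j - 1], acc[i - 1, j - 1])
    return float(acc[n, m])


def pairwise_dtw(scores: np.ndarray, subject_ids=None, local_cost: str = "abs") -> DistanceMatrix:
    """All-pairs DTW for equal-length rows of a trajectory matrix.

    The accumulated-cost recursion runs once over the (t x t) grid with the
    pair axis vectorized, so the cost is O(t^2) NumPy operations on
    length-``n_pairs`` arrays rather than a Python loop per pair.

    Rows containing NaN are rejected; complete series are an inclusion
    requirement upstream.
    """
    if hasattr(scores, "scores"):  # accept a TrajectoryMatrix directly
        if subject_ids is None:
            subject_ids = scores.subject_ids
        scores = scores.scores
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 subjects")
    if np.any(np.isnan(X)):
        raise MissingDataError("trajectory matrix contains NaN rows; drop incomplete subjects")

    n, t = X.shape
    iu, ju = np.triu_indices(n, k=1)
    A = X[iu]  # (p, t)
    B = X[ju]
    # cost[p, i, j] computed lazily column-by-column inside the DP.
    acc = np.full((len(iu), t + 1, t + 1), np.inf)
    acc[:, 0, 0] = 0.0
    for i in range(1, t + 1):
        ai = A[:, i - 1][:, None]  # (p, 1)
        cost_row = np.abs(ai - B)  # (p, t)
        if local_cost == "sq":
            cost_row = cost_row**2
        for j in range(1, t + 1):
            prev = np.minimum(
                np.minimum(acc[:, i - 1, j], acc[:, i, j - 1]), acc[:, i - 1, j - 1]
            )
            acc[:, i, j] = cost_row[:, j - 1] + prev
    d = np.zeros((n, n))
    d[iu, ju] = acc[:, t, t]
    d[ju, iu] = acc[:, t, t]
    return DistanceMatrix(values=d, metric_name=f"dtw_{local_cost}", subject_ids=subject_ids)
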