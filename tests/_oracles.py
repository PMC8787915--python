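"""Independent brute-force oracles used across the test suite.

These deliberately avoid the library's own algorithms: DTW by exhaustive
enumeration of monotone warping paths, and agglomerative linkage by a
naive O(n^3) re-scan that recomputes every inter-cluster distance from
the original dissimilarities at every step.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

import numpy as np


def dtw_bruteforce(a, b) -> float:
    """Minimum path cost over all monotone warping paths (|.| local cost)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> float:
        cost = abs(a[i] - b[j])
        if i == 0 and j == 0:
            return cost
        cands = []
        if i > 0:
            cands.append(best(i - 1, j))
        if j > 0:
            cands.append(best(i, j - 1))
        if i > 0 and j > 0:
            cands.append(best(i - 1, j - 1))
        return cost + min(cands)

    return best(len(a) - 1, len(b) - 1)


def naive_linkage(D: np.ndarray, method: str):
    """Naive agglomeration: recompute cluster distances from scratch.

    Returns merge tuples (a, b, height, size) with scipy-style cluster
    ids and the same lowest-id tie-break as the package implementation.
    """
    n = D.shape[0]
    S = D.astype(float) ** 2 if method == "ward2" else D.astype(float).copy()
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n

    def cdist(A, B):
        if method == "upgma":
            return np.mean([S[a, b] for a in A for b in B])
        nA, nB = len(A), len(B)
        d_ab = sum(S[a, b] for a in A for b in B) / (nA * nB)
        d_aa = (
            2 * sum(S[a, b] for a, b in combinations(A, 2)) / (nA * nA) if nA > 1 else 0.0
        )
        d_bb = (
            2 * sum(S[a, b] for a, b in combinations(B, 2)) / (nB * nB) if nB > 1 else 0.0
        )
        return nA * nB / (nA + nB) * (2 * d_ab - d_aa - d_bb)

    for _ in range(n - 1):
        ids = sorted(clusters)
        best = None
        for a, b in combinations(ids, 2):
            d = cdist(clusters[a], clusters[b])
            if best is None or d < best[0] - 1e-11 or (abs(d - best[0]) <= 1e-11 and (a, b) < best[1:]):
                best = (d, a, b)
        d, a, b = best
        h = float(np.sqrt(d)) if method == "ward2" else float(d)
        merges.append((a, b, h, len(clusters[a]) + len(clusters[b])))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


def rm_anova_textbook(Y: np.ndarray, groups: np.ndarray):
    """Textbook mixed-design sums-of-squares decomposition, written the
    long way (explicit loops) as an oracle for the vectorized version."""
    n, t = Y.shape
    uniq = list(dict.fromkeys(groups))
    grand = Y.mean()
    ss_time = sum(n * (Y[:, j].mean() - grand) ** 2 for j in range(t))
    ss_int = 0.0
    for g in uniq:
        rows = Y[np.asarray(groups) == g]
        for j in range(t):
            ss_int += len(rows) * (
                rows[:, j].mean() - rows.mean() - Y[:, j].mean() + grand
            ) ** 2
    ss_subj = 0.0
    for g in uniq:
        rows = Y[np.asarray(groups) == g]
        for i in range(len(rows)):
            ss_subj += t * (rows[i].mean() - rows.mean()) ** 2
    ss_group = sum(
        t * (Y[np.asarray(groups) == g]).shape[0] * ((Y[np.asarray(groups) == g]).mean() - grand) ** 2
        for g in uniq
    )
    ss_total = ((Y - grand) ** 2).sum()
    ss_err = ss_total - ss_time - ss_int - ss_subj - ss_group
    df_err = (n - len(uniq)) * (t - 1)
    F_time = (ss_time / (t - 1)) / (ss_err / df_err)
    F_int = (ss_int / ((len(uniq) - 1) * (t - 1))) / (ss_err / df_err)
    return F_time, F_int
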