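"""Hierarchical agglomerative clustering of trajectory dissimilarities.

Implements Lance–Williams agglomeration with the three linkages used for
progression phenotyping:

* ``ward2`` (default) — Ward's criterion applied to squared
  dissimilarities, with merge heights reported on the original scale
  (square root of the working-scale minimum);
* ``ward1`` — the same recurrence applied to the dissimilarities
  themselves;
* ``upgma`` — unweighted average linkage.

Ties in the minimum inter-cluster distance are broken toward the pair with
the lowest cluster indices (creation order), which makes the merge tree
deterministic across platforms.  Cluster-number selection uses average
silhouette width computed directly from the dissimilarity matrix, and a
two-cluster solution is named Moderate/Fast Decliners (MD/FD) from the
mean fitted slope of each cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import silhouette_samples

from .dtw import DistanceMatrix

__all__ = [
    "MergeRecord",
    "ClusterAssignment",
    "hierarchical_cluster",
    "linkage_merge_tree",
    "cut_merge_tree",
    "silhouette_select_k",
    "name_phenotypes",
    "merge_tree_to_newick",
]

LINKAGES = ("ward2", "ward1", "upgma")


@dataclass(frozen=True)
class MergeRecord:
    """One agglomeration step: clusters ``a`` and ``b`` merge at ``height``.

    Cluster ids follow the scipy convention: leaves are 0..n-1 and the
    cluster created by merge step s gets id n + s.
    """

    a: int
    b: int
    height: float
    size: int


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # per-subject cluster index in [0, k)
    k: int
    linkage_name: str
    merge_tree: list[MergeRecord]
    phenotype_map: dict[int, str] | None = None
    subject_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min() < 0 or self.labels.max() >= self.k:
            raise ValueError("labels must lie in [0, k)")

    @property
    def phenotypes(self) -> np.ndarray:
        """Per-subject MD/FD phenotype names (requires phenotype_map)."""
        if self.phenotype_map is None:
            raise ValueError("phenotype_map not set; call name_phenotypes first")
        return np.array([self.phenotype_map[int(c)] for c in self.labels])


def _lw_update(method: str, s_ik, s_jk, s_ij, ni, nj, nk):
    """Lance–Williams distance from cluster k to the merged cluster i∪j."""
    if method in ("ward2", "ward1"):
        tot = ni + nj + nk
        return ((ni + nk) * s_ik + (nj + nk) * s_jk - nk * s_ij) / tot
    if method == "upgma":
        return (ni * s_ik + nj * s_jk) / (ni + nj)
    raise ValueError(f"unknown linkage {method!r}")


def linkage_merge_tree(D: DistanceMatrix, linkage_name: str = "ward2") -> list[MergeRecord]:
    """Full agglomeration of ``D`` under the requested linkage.

    Works on the linkage's working scale (squared dissimilarities for
    ward2) and reports heights back on the original scale.  Minimum search
    uses exact equality for the tie-break: among all pairs attaining the
    minimum, the lexicographically smallest (a, b) by cluster id merges.
    """
    if linkage_name not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    n = D.n
    S = D.values.astype(float).copy()
    if linkage_name == "ward2":
        S = S**2
    np.fill_diagonal(S, np.inf)

    ids = list(range(n))  # active cluster ids, in creation order
    sizes = {i: 1 for i in range(n)}
    merges: list[MergeRecord] = []
    for step in range(n - 1):
        m = len(ids)
        iu, ju = np.triu_indices(m, k=1)
        vals = S[iu, ju]
        smin = vals.min()
        hits = np.flatnonzero(vals == smin)
        # lowest cluster-id pair first (ids are in creation order)
        pos = min(hits, key=lambda h: tuple(sorted((ids[iu[h]], ids[ju[h]]))))
        i, j = int(iu[pos]), int(ju[pos])
        ida, idb = ids[i], ids[j]
        height = float(np.sqrt(smin)) if linkage_name == "ward2" else float(smin)
        new_size = sizes[ida] + sizes[idb]
        merges.append(MergeRecord(min(ida, idb), max(ida, idb), height, new_size))

        # distances from every other active cluster to the merged one
        others = [t for t in range(m) if t not in (i, j)]
        if others:
            nk = np.array([sizes[ids[t]] for t in others], dtype=float)
            new_row = _lw_update(
                linkage_name, S[i, others], S[j, others], smin, sizes[ida], sizes[idb], nk
            )
        # collapse: overwrite row i with merged cluster, delete row j
        new_id = n + step
        for t, v in zip(others, new_row if others else []):
            S[i, t] = S[t, i] = v
        S = np.delete(np.delete(S, j, axis=0), j, axis=1)
        ids[i] = new_id
        del ids[j]
        sizes[new_id] = new_size
    return merges


def cut_merge_tree(merges: list[MergeRecord], n: int, k: int) -> np.ndarray:
    """Labels in [0, k) from the first n-k merges; label order follows the
    smallest subject index in each cluster."""
    parent = list(range(n + len(merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step, rec in enumerate(merges[: n - k]):
        new_id = n + step
        parent[find(rec.a)] = new_id
        parent[find(rec.b)] = new_id
    roots = np.array([find(i) for i in range(n)])
    order: dict[int, int] = {}
    for r in roots:  # first appearance = smallest subject index
        if r not in order:
            order[r] = len(order)
    return np.array([order[r] for r in roots])


def hierarchical_cluster(
    D: DistanceMatrix, linkage_name: str = "ward2", k: int = 2
) -> ClusterAssignment:
    """Agglomerate ``D`` and cut the tree at ``k`` clusters."""
    n = D.n
    if not 2 <= k <= n - 1:
        raise ValueError(f"k must lie in [2, {n - 1}]")
    merges = linkage_merge_tree(D, linkage_name)
    labels = cut_merge_tree(merges, n, k)
    return ClusterAssignment(
        labels=labels,
        k=k,
        linkage_name=linkage_name,
        merge_tree=merges,
        subject_ids=D.subject_ids,
    )


def silhouette_select_k(
    D: DistanceMatrix, k_range=(2, 3, 4), linkage_name: str = "ward2"
) -> tuple[int, dict[int, float]]:
    """Average silhouette width per k; returns (argmax k, widths).

    Silhouettes are computed from the dissimilarity matrix directly;
    singleton clusters contribute a width of 0.
    """
    if D.values.max() == 0:
        raise ValueError("degenerate all-zero distance matrix: silhouette undefined")
    widths: dict[int, float] = {}
    for k in k_range:
        labels = hierarchical_cluster(D, linkage_name, k).labels
        s = silhouette_samples(D.values, labels, metric="precomputed")
        widths[int(k)] = float(s.mean())
    best = max(widths, key=lambda k: (widths[k], -k))
    return best, widths


def fitted_slopes(scores: np.ndarray, visit_months: np.ndarray) -> np.ndarray:
    """Per-subject least-squares slope (score units per year)."""
    t = np.asarray(visit_months, dtype=float) / 12.0
    X = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(X, np.asarray(scores, dtype=float).T, rcond=None)
    return coef[1]


def name_phenotypes(assignment: ClusterAssignment, trajectories) -> ClusterAssignment:
    """Name the two clusters MD/FD from their mean fitted slopes.

    The cluster with the more negative mean slope is the Fast Decliners
    (FD); ties break toward the cluster with the larger mean baseline
    score being MD.
    """
    if assignment.k != 2:
        raise ValueError("phenotype naming requires exactly 2 clusters")
    scores = np.asarray(trajectories.scores, dtype=float)
    slopes = fitted_slopes(scores, trajectories.visit_months)
    mean_slope = [slopes[assignment.labels == c].mean() for c in (0, 1)]
    if not np.isclose(mean_slope[0], mean_slope[1], rtol=1e-12, atol=1e-12):
        fd = int(np.argmin(mean_slope))
    else:
        baseline = [scores[assignment.labels == c, 0].mean() for c in (0, 1)]
        fd = int(np.argmin(baseline))  # larger baseline = MD
    assignment.phenotype_map = {fd: "FD", 1 - fd: "MD"}
    return assignment


def merge_tree_to_newick(merges: list[MergeRecord], n: int, leaf_names=None) -> str:
    """Newick string with branch lengths = parent height − child height."""
    if leaf_names is None:
        leaf_names = [f"S{i:04d}" for i in range(n)]
    height = {i: 0.0 for i in range(n)}
    node = {i: str(leaf_names[i]) for i in range(n)}
    for step, rec in enumerate(merges):
        nid = n + step
        la = max(rec.height - height[rec.a], 0.0)
        lb = max(rec.height - height[rec.b], 0.0)
        node[nid] = f"({node[rec.a]}:{la:.6g},{node[rec.b]}:{lb:.6g})"
        height[nid] = rec.height
    return node[n + len(merges) - 1] + ";"
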