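"""Statistical validation of progression phenotypes.

Covers the post-clustering inference and group comparisons used to
validate an MD/FD split: a pipeline-honest permutation test for cluster
separation, classical two-way mixed-design (repeated-measures) ANOVA on
secondary cognitive scales, Welch t / Wilcoxon rank-sum group
differences, CSF p-tau positivity, and Pearson chi-square contingency
analysis.

The permutation test replaces post-selection inference machinery with a
null that honestly repeats the clustering pipeline: residuals about the
per-visit mean curve are permuted within visits, the permuted cohort is
re-clustered, and the between-cluster statistic recomputed.  Under a null
cohort with exchangeable within-visit residuals this is an exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .cluster import hierarchical_cluster
from .dtw import dtw_distance, pairwise_dtw

__all__ = [
    "RMAnovaResult",
    "ContingencyResult",
    "permutation_cluster_test",
    "rm_anova",
    "group_difference",
    "tau_positive",
    "chi_square",
    "PTAU_POSITIVITY_CUTOFF",
]

#: CSF p-tau181 positivity threshold (pg/mL); T+ is strictly above.
PTAU_POSITIVITY_CUTOFF = 21.8


class DegenerateDataError(ValueError):
    """Raised when a test's inputs carry no usable variation."""


@dataclass(frozen=True)
class RMAnovaResult:
    F_time: float
    df_time: tuple[int, int]
    p_time: float
    F_interaction: float
    df_interaction: tuple[int, int]
    p_interaction: float


@dataclass(frozen=True)
class ContingencyResult:
    table: np.ndarray
    chi2: float
    df: int
    p: float


def _between_cluster_statistic(scores: np.ndarray, labels: np.ndarray) -> float:
    """DTW distance between the two cluster-mean trajectories."""
    m0 = scores[labels == labels.min()].mean(axis=0)
    m1 = scores[labels == labels.max()].mean(axis=0)
    return dtw_distance(m0, m1)


def permutation_cluster_test(
    trajectories,
    labels: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    linkage_name: str = "ward2",
) -> tuple[float, float, np.ndarray]:
    """Permutation test for separation between two trajectory clusters.

    Parameters
    ----------
    trajectories
        TrajectoryMatrix or (n, t) score array.
    labels
        Two-group labels.  When None (the pipeline-honest default) the
        observed labels are produced by clustering the data with the same
        DTW + linkage pipeline used for the null.
    n_perm
        Number of permutations (>= 100).

    Returns
    -------
    (p, observed_statistic, null_statistics)
    """
    scores = np.asarray(getattr(trajectories, "scores", trajectories), dtype=float)
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")

    def cluster_labels(X: np.ndarray) -> np.ndarray:
        return hierarchical_cluster(pairwise_dtw(X), linkage_name, k=2).labels

    internal = labels is None
    if internal:
        # pipeline-honest mode: observed labels come from the same
        # clustering used for the null, so singleton clusters are kept on
        # both sides (required for exact exchangeability)
        labels = cluster_labels(scores)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError("permutation test requires exactly two groups")
    if not internal and min((labels == u).sum() for u in uniq) < 2:
        raise DegenerateDataError("each cluster must contain >= 2 subjects")

    observed = _between_cluster_statistic(scores, (labels == uniq[1]).astype(int))

    rng = np.random.default_rng(seed)
    col_mean = scores.mean(axis=0, keepdims=True)
    resid = scores - col_mean
    n, t = scores.shape
    null = np.empty(n_perm)
    for p_i in range(n_perm):
        perm = np.empty_like(resid)
        for j in range(t):  # independent within-visit shuffles
            perm[:, j] = resid[rng.permutation(n), j]
        Xp = col_mean + perm
        lp = cluster_labels(Xp)
        null[p_i] = _between_cluster_statistic(Xp, lp)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return float(p), float(observed), null


def rm_anova(scores: np.ndarray, group_labels: np.ndarray, time_labels=None) -> RMAnovaResult:
    """Two-way mixed-design ANOVA: between = group, within = time.

    Classical sums-of-squares partition with subject as the within-error
    stratum; no sphericity correction.  Returns the main effect of time
    and the time-by-group interaction, with degrees of freedom
    F(t-1, (n-g)(t-1)) and F((g-1)(t-1), (n-g)(t-1)).
    """
    Y = np.asarray(scores, dtype=float)
    g_lab = np.asarray(group_labels)
    if Y.ndim != 2:
        raise ValueError("scores must be subject x time")
    if np.any(np.isnan(Y)):
        raise ValueError("unbalanced/missing panel: rm_anova requires complete data")
    n, t = Y.shape
    groups = np.unique(g_lab)
    g = groups.size
    if g < 2 or t < 2:
        raise ValueError("need >= 2 groups and >= 2 time points")

    grand = Y.mean()
    subj_mean = Y.mean(axis=1)
    time_mean = Y.mean(axis=0)
    group_mean = np.array([Y[g_lab == gr].mean() for gr in groups])
    cell_mean = np.vstack([Y[g_lab == gr].mean(axis=0) for gr in groups])  # g x t
    n_per = np.array([(g_lab == gr).sum() for gr in groups])

    ss_time = n * np.sum((time_mean - grand) ** 2)
    ss_group = t * np.sum(n_per * (group_mean - grand) ** 2)
    # interaction = cell variation not explained by the two main effects
    ss_interaction = (
        np.sum(n_per[:, None] * (cell_mean - group_mean[:, None] - time_mean[None, :] + grand) ** 2)
    )
    ss_subj_within = t * np.sum(
        (subj_mean - np.array([group_mean[np.flatnonzero(groups == gl)[0]] for gl in g_lab])) ** 2
    )
    ss_total = np.sum((Y - grand) ** 2)
    ss_err_within = ss_total - ss_group - ss_subj_within - ss_time - ss_interaction
    ss_err_within = max(ss_err_within, 0.0)

    df_time = t - 1
    df_int = (g - 1) * (t - 1)
    df_err = (n - g) * (t - 1)
    ms_err = ss_err_within / df_err if df_err > 0 else 0.0

    def f_and_p(ss_eff: float, df_eff: int) -> tuple[float, float]:
        if ms_err == 0.0:
            return (0.0, 1.0) if ss_eff <= 1e-12 else (np.inf, 0.0)
        F = (ss_eff / df_eff) / ms_err
        return float(F), float(sps.f.sf(F, df_eff, df_err))

    F_t, p_t = f_and_p(ss_time, df_time)
    F_i, p_i = f_and_p(ss_interaction, df_int)
    return RMAnovaResult(F_t, (df_time, df_err), p_t, F_i, (df_int, df_err), p_i)


def group_difference(values, labels, method: str = "t") -> tuple[float, float]:
    """Two-sided two-group difference: Welch t or Wilcoxon rank-sum.

    Returns (statistic, p).  Used for demographic comparisons and the
    biomarker redundancy analyses.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError("group_difference requires exactly two groups")
    x = values[labels == uniq[0]]
    y = values[labels == uniq[1]]
    if len(x) < 2 or len(y) < 2:
        raise DegenerateDataError("each group must have n >= 2")
    if method == "t":
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
            raise DegenerateDataError("zero variance in both groups")
        stat, p = sps.ttest_ind(x, y, equal_var=False)
    elif method == "ranksum":
        stat, p = sps.ranksums(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(stat), float(p)


def tau_positive(ptau, cutoff: float = PTAU_POSITIVITY_CUTOFF):
    """CSF p-tau positivity: strictly above ``cutoff`` (pg/mL).

    Returns a boolean array; NaN entries are returned as a masked
    (missing) flag via the second output.
    """
    ptau = np.asarray(ptau, dtype=float)
    missing = np.isnan(ptau)
    positive = np.where(missing, False, ptau > cutoff)
    if ptau.ndim == 0:
        if missing:
            raise ValueError("missing p-tau value")
        return bool(positive)
    return positive, missing


def chi_square(table) -> ContingencyResult:
    """Pearson chi-square on an r x c count table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or np.any(table < 0):
        raise ValueError("table must be a 2-D non-negative count matrix")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero row/column margin")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    return ContingencyResult(table=table, chi2=float(chi2), df=int(df), p=float(p))
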