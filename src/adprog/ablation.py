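"""Biomarker-combination ablation harness and ROC statistics.

Runs the multimodal classifier over AT(N) biomarker subsets (N, A(N),
T(N), AT(N), N+ICV, MRI-only, ...) under identical fold splits and seeds,
so accuracy differences are attributable to the inputs alone; computes
ROC curves, Mann–Whitney AUCs, DeLong comparisons of correlated AUCs,
single-biomarker logistic / RBF-SVM baselines, and the biomarker
redundancy analysis (do A(N)-predicted phenotypes differ in p-tau; do
T(N)-predicted phenotypes differ in Aβ).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .penet import MODALITY_COMBINATIONS, PENetSpec, TrainConfig, stratified_folds, train_cv
from .stats import DegenerateDataError, group_difference

__all__ = [
    "AblationResult",
    "auc",
    "roc_points",
    "delong_test",
    "delong_variance",
    "run_ablation",
    "scalar_baseline",
    "redundancy_analysis",
]


@dataclass
class AblationResult:
    combination: str
    accuracy_mean: float
    accuracy_sd: float
    pooled_auc: float
    roc: np.ndarray  # (m, 2) of (FPR, TPR), threshold-ordered
    probabilities: np.ndarray  # pooled out-of-fold P(FD)
    predictions: np.ndarray
    fold_accuracies: np.ndarray


def auc(scores, labels) -> float:
    """AUC as the Mann–Whitney U statistic / (n1*n0), ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = sps.rankdata(scores)  # midranks handle ties as 1/2
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_points(scores, labels) -> np.ndarray:
    """ROC curve (FPR, TPR) from (0,0) to (1,1), ordered by threshold."""
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    pts = np.column_stack([fpr, tpr])
    if not np.allclose(pts[0], [0, 0]):
        pts = np.vstack([[0.0, 0.0], pts])
    if not np.allclose(pts[-1], [1, 1]):
        pts = np.vstack([pts, [1.0, 1.0]])
    return pts


def _placements(scores, labels):
    """DeLong structural components (placement values) V10, V01."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos, neg = s[y == 1], s[y == 0]
    # V10[i] = P_hat(pos_i > neg) with ties 1/2; V01[j] symmetric
    v10 = np.array([((p > neg).sum() + 0.5 * (p == neg).sum()) / len(neg) for p in pos])
    v01 = np.array([((pos > q).sum() + 0.5 * (pos == q).sum()) / len(pos) for q in neg])
    return v10, v01


def delong_variance(scores, labels) -> float:
    """DeLong variance estimate of a single empirical AUC."""
    v10, v01 = _placements(scores, labels)
    if len(v10) < 2 or len(v01) < 2:
        raise ValueError("DeLong variance needs >= 2 subjects per class")
    return float(np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01))


def delong_test(scores_a, scores_b=None, labels=None) -> tuple[float, float, float]:
    """DeLong z test.

    With ``scores_b`` given: paired comparison of two correlated AUCs on
    identical subjects.  With ``scores_b=None``: single-model test of
    AUC(scores_a) against the chance value 0.5.

    Returns (z, two-sided p, AUC difference — vs 0.5 for single-model).
    """
    if labels is None:
        raise ValueError("labels are required")
    labels = np.asarray(labels).astype(int)
    a = np.asarray(scores_a, dtype=float)
    if scores_b is None:
        auc_a = auc(a, labels)
        var = delong_variance(a, labels)
        diff = auc_a - 0.5
    else:
        b = np.asarray(scores_b, dtype=float)
        if len(a) != len(b) or len(a) != len(labels):
            raise ValueError("paired DeLong requires scores on identical subjects")
        auc_a, auc_b = auc(a, labels), auc(b, labels)
        va10, va01 = _placements(a, labels)
        vb10, vb01 = _placements(b, labels)
        n1, n0 = len(va10), len(va01)
        s10 = np.cov(np.vstack([va10, vb10]))
        s01 = np.cov(np.vstack([va01, vb01]))
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1 + (
            s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
        ) / n0
        diff = auc_a - auc_b
    if var <= 0:
        return 0.0, 1.0, float(diff)
    z = diff / np.sqrt(var)
    p = 2 * sps.norm.sf(abs(z))
    return float(z), float(p), float(diff)


def run_ablation(
    cohort,
    combinations,
    spec: PENetSpec,
    config: TrainConfig,
    labels: np.ndarray | None = None,
) -> list[AblationResult]:
    """Train one cross-validated model per biomarker combination.

    All combinations share identical stratified folds and seeds (paired
    design); only ``enabled_modalities`` varies.
    """
    labels_arr = cohort.labels if labels is None else np.asarray(labels, dtype=int)
    folds = stratified_folds(labels_arr, config.folds, config.seed)
    results = []
    for combo in combinations:
        if combo not in MODALITY_COMBINATIONS:
            raise ValueError(
                f"unknown combination {combo!r}; known: {sorted(MODALITY_COMBINATIONS)}"
            )
        combo_spec = replace(spec, enabled_modalities=MODALITY_COMBINATIONS[combo])
        fold_results, summary = train_cv(cohort, combo_spec, config, labels_arr, folds)
        results.append(
            AblationResult(
                combination=combo,
                accuracy_mean=summary.accuracy_mean,
                accuracy_sd=summary.accuracy_sd,
                pooled_auc=summary.pooled_auc,
                roc=roc_points(summary.pooled_probabilities, labels_arr),
                probabilities=summary.pooled_probabilities,
                predictions=summary.pooled_predictions,
                fold_accuracies=np.array([fr.accuracy for fr in fold_results]),
            )
        )
    return results


def _svm_imaging_features(volumes: np.ndarray, fdg: np.ndarray | None) -> np.ndarray:
    """Downsampled (8^3) standardized volumes, flattened, + FDG scalar."""
    feats = []
    for v in volumes:
        small = ndimage.zoom(v.astype(float), [8 / s for s in v.shape], order=1)
        small = (small - small.mean()) / (small.std() or 1.0)
        feats.append(small.ravel())
    X = np.asarray(feats)
    if fdg is not None:
        X = np.column_stack([X, fdg])
    return X


def scalar_baseline(
    features: np.ndarray,
    labels: np.ndarray,
    model: str = "logistic",
    folds: list[np.ndarray] | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Cross-validated accuracy of a shallow baseline classifier.

    ``model`` is ``"logistic"`` or ``"svm_rbf"``.  Returns
    (accuracy mean, accuracy sd, out-of-fold probability/score vector).
    Constant feature columns are dropped with a warning.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels).astype(int)
    keep = X.std(axis=0) > 0
    if not keep.all():
        import warnings

        warnings.warn(f"dropping {int((~keep).sum())} constant feature column(s)")
        X = X[:, keep]
    if X.shape[1] == 0:
        raise ValueError("no informative features remain")
    if folds is None:
        folds = stratified_folds(y, n_folds, seed)

    accs, scores = [], np.full(len(y), np.nan)
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        if model == "logistic":
            clf = make_pipeline(StandardScaler(), LogisticRegression(max_iter=2000))
        elif model == "svm_rbf":
            clf = make_pipeline(StandardScaler(), SVC(kernel="rbf"))
        else:
            raise ValueError(f"unknown baseline model {model!r}")
        clf.fit(X[train_idx], y[train_idx])
        pred = clf.predict(X[test_idx])
        accs.append(float((pred == y[test_idx]).mean()))
        if model == "logistic":
            scores[test_idx] = clf.predict_proba(X[test_idx])[:, 1]
        else:
            scores[test_idx] = clf.decision_function(X[test_idx])
    accs = np.array(accs)
    return float(accs.mean()), float(accs.std(ddof=1)), scores


def redundancy_analysis(
    cohort,
    predictions_an: np.ndarray,
    predictions_tn: np.ndarray,
    method: str = "t",
) -> dict[str, tuple[float, float]]:
    """Cross-biomarker redundancy check on model-predicted phenotypes.

    Tests whether phenotypes predicted from A(N) inputs differ in the
    held-out CSF p-tau, and whether phenotypes predicted from T(N) inputs
    differ in the held-out CSF Aβ.  Returns
    ``{"ptau_given_AN": (stat, p), "abeta_given_TN": (stat, p)}``.
    """
    out = {}
    for name, preds, biomarker in [
        ("ptau_given_AN", np.asarray(predictions_an), cohort.biomarkers["ptau"].to_numpy()),
        ("abeta_given_TN", np.asarray(predictions_tn), cohort.biomarkers["abeta"].to_numpy()),
    ]:
        if np.unique(preds).size < 2:
            raise DegenerateDataError(f"{name}: a predicted group is empty")
        out[name] = group_difference(biomarker, preds, method=method)
    return out
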