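"""Atrophy-based AD subtyping from regional volumes.

Subtypes follow the hippocampal-to-cortical volume ratio convention:
subjects with an HV:CTV ratio strictly above the within-sample 75th
percentile are Hippocampal-Sparing (HpSp), strictly below the 25th
percentile Limbic-Predominant (LP), and the remainder typical AD (tAD).
Percentiles use linear interpolation between order statistics; subjects
exactly at a threshold fall to tAD.  The subtype-by-phenotype association
is a Pearson chi-square on the 3x2 contingency table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import ContingencyResult, chi_square

__all__ = [
    "SubtypeAssignment",
    "compute_ratio",
    "assign_subtypes",
    "associate",
    "SUBTYPE_NAMES",
]

SUBTYPE_NAMES = ("HpSp", "LP", "tAD")


@dataclass
class SubtypeAssignment:
    subject_id: str
    hv_ctv_ratio: float
    subtype: str
    threshold_25: float
    threshold_75: float


def compute_ratio(hippocampal_volume, cortical_total_volume):
    """HV:CTV ratio; both volumes must be positive (mm^3)."""
    hv = np.asarray(hippocampal_volume, dtype=float)
    ctv = np.asarray(cortical_total_volume, dtype=float)
    if np.any(hv <= 0) or np.any(ctv <= 0):
        raise ValueError("volumes must be positive")
    ratio = hv / ctv
    return float(ratio) if ratio.ndim == 0 else ratio


def assign_subtypes(
    ratios,
    subject_ids=None,
    thresholds: tuple[float, float] | None = None,
) -> list[SubtypeAssignment]:
    """Percentile-rule subtyping of HV:CTV ratios.

    ``thresholds`` overrides the within-sample (25th, 75th) percentiles
    with external reference values.
    """
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size < 4:
        raise ValueError("need >= 4 subjects for quartile thresholds")
    if subject_ids is None:
        subject_ids = [f"S{i:04d}" for i in range(ratios.size)]
    if thresholds is None:
        q25, q75 = np.percentile(ratios, [25, 75])  # linear interpolation
    else:
        q25, q75 = thresholds
    if q25 == q75:
        warnings.warn("degenerate ratio distribution: all subjects assigned tAD")
    out = []
    for sid, r in zip(subject_ids, ratios):
        if r > q75:
            sub = "HpSp"
        elif r < q25:
            sub = "LP"
        else:
            sub = "tAD"
        out.append(SubtypeAssignment(str(sid), float(r), sub, float(q25), float(q75)))
    return out


def region_mean_difference_table(volumes: np.ndarray, group_labels,
                                 masks: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
    """Per-region mean-intensity difference between two groups.

    A deliberately simple, clearly-labelled qualitative stand-in for
    voxelwise morphometric contrasts: for each nominal phantom region it
    reports the group means of the mean region intensity and their
    difference.  It makes no claim of spatial inference.
    """
    from .synthetic import phantom_region_masks

    labels = np.asarray(group_labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError("region contrast requires exactly two groups")
    if masks is None:
        masks = phantom_region_masks(volumes.shape[1:])
    rows = []
    for region, mask in masks.items():
        per_subject = volumes[:, mask].mean(axis=1)
        m0 = per_subject[labels == uniq[0]].mean()
        m1 = per_subject[labels == uniq[1]].mean()
        rows.append({"region": region, f"mean_{uniq[0]}": m0, f"mean_{uniq[1]}": m1,
                     "difference": m0 - m1})
    return pd.DataFrame(rows)


def associate(subtypes, phenotypes) -> tuple[ContingencyResult, pd.DataFrame]:
    """3x2 subtype-by-phenotype contingency table and chi-square test.

    ``subtypes`` may be SubtypeAssignment objects or subtype name strings;
    ``phenotypes`` are per-subject MD/FD labels in the same order.
    """
    names = [s.subtype if isinstance(s, SubtypeAssignment) else str(s) for s in subtypes]
    phenotypes = [str(p) for p in phenotypes]
    if len(names) != len(phenotypes):
        raise ValueError("subtype and phenotype label sets must cover the same subjects")
    table = pd.crosstab(
        pd.Categorical(names, categories=SUBTYPE_NAMES),
        pd.Categorical(phenotypes, categories=sorted(set(phenotypes))),
        dropna=False,
    )
    counts = table.to_numpy()
    nonzero_rows = counts.sum(axis=1) > 0
    if not nonzero_rows.all():
        # an unpopulated subtype row is a margin error for the chi-square
        raise ValueError(
            f"empty subtype row(s): {[SUBTYPE_NAMES[i] for i in np.flatnonzero(~nonzero_rows)]}"
        )
    return chi_square(counts), table
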