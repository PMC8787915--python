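"""End-to-end pipeline driver: simulate → filter → cluster → stats →
train/ablate → subtype, with per-stage persistence, resumability, and a
reproducible run report.

Each stage writes its artifacts into the output directory and is skipped
on re-run if those artifacts already exist; because the cohort is
regenerated deterministically from the config seed, deleting any
intermediate artifact and resuming reproduces identical results.  The
global seed fans out to per-stage seeds through a keyed hash of the stage
name, so stage-level randomness is independent of execution order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ablation import redundancy_analysis, run_ablation
from .cluster import (
    hierarchical_cluster,
    merge_tree_to_newick,
    name_phenotypes,
    silhouette_select_k,
)
from .dtw import pairwise_dtw
from .penet import PENetSpec, TrainConfig
from .stats import (
    PTAU_POSITIVITY_CUTOFF,
    chi_square,
    group_difference,
    permutation_cluster_test,
    rm_anova,
    tau_positive,
)
from .subtypes import assign_subtypes, associate, compute_ratio
from .synthetic import (
    ABETA_CUTOFF_PG_ML,
    SUVR_CUTOFF,
    Cohort,
    CohortConfig,
    apply_inclusion_filter,
    generate_cohort,
    write_cohort,
)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "stage_seed"]

log = logging.getLogger("adprog")


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed from a keyed hash of the stage name (< 2^31)."""
    digest = hashlib.blake2b(f"{global_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "little") % (2**31)


@dataclass
class PipelineConfig:
    """One document describing a full run; every study constant is a key."""

    cohort: CohortConfig = field(default_factory=lambda: CohortConfig(synergy_coefficient=1.5))
    spec: PENetSpec = field(default_factory=PENetSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    combinations: tuple[str, ...] = ("N", "T(N)", "AT(N)")
    abeta_cutoff_pg_ml: float = ABETA_CUTOFF_PG_ML
    suvr_cutoff: float = SUVR_CUTOFF
    ptau_cutoff_pg_ml: float = PTAU_POSITIVITY_CUTOFF
    linkage: str = "ward2"
    k_range: tuple[int, ...] = (2, 3, 4)
    n_perm: int = 200
    write_volumes: bool = False
    make_figures: bool = False
    seed: int = 0

    def resolved(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        return enc(dataclasses.asdict(self))


@dataclass
class RunReport:
    config: dict
    version: str = __version__
    stages: list[dict] = field(default_factory=list)
    metrics: dict = field(default_factory=dict)
    ok: bool = True

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "ok": self.ok,
                "stages": self.stages,
                "metrics": self.metrics,
                "config": self.config,
            },
            indent=2,
            default=float,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunReport:
    """Execute all stages; on stage failure, record it and skip downstream."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.resolved())
    state: dict = {}

    stages = [
        ("simulate", _stage_simulate),
        ("filter", _stage_filter),
        ("cluster", _stage_cluster),
        ("stats", _stage_stats),
        ("ablate", _stage_ablate),
        ("subtype", _stage_subtype),
    ]
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            outputs = fn(config, out, state, report.metrics)
            status = "ok"
        except Exception as exc:  # noqa: BLE001 - report and stop
            log.exception("stage %s failed", name)
            report.stages.append(
                {"name": name, "status": "failed", "error": f"{type(exc).__name__}: {exc}",
                 "runtime_s": round(time.perf_counter() - t0, 3)}
            )
            report.ok = False
            break
        report.stages.append(
            {
                "name": name,
                "status": status,
                "runtime_s": round(time.perf_counter() - t0, 3),
                "outputs": {str(p.name): _sha256(p) for p in outputs},
            }
        )
    (out / "run_report.json").write_text(report.to_json())
    return report


# ----------------------------------------------------------------------
# Stages.  Each returns the list of artifact paths it guarantees exist.
# ----------------------------------------------------------------------

def _stage_simulate(config: PipelineConfig, out: Path, state: dict, metrics: dict) -> list[Path]:
    cohort_cfg = dataclasses.replace(config.cohort, seed=stage_seed(config.seed, "simulate"))
    cohort = generate_cohort(cohort_cfg)
    state["cohort"] = cohort
    files = [out / f for f in ["trajectories.csv", "biomarkers.csv", "regional_volumes.csv",
                               "demographics.csv", "true_class.csv", "manifest.json"]]
    if not all(f.exists() for f in files):
        write_cohort(cohort, out, write_volumes=config.write_volumes)
    metrics["simulate"] = {
        "n_subjects": cohort.n_subjects,
        "n_fd": int(cohort.labels.sum()),
        "n_md": int((1 - cohort.labels).sum()),
    }
    return files


def _stage_filter(config: PipelineConfig, out: Path, state: dict, metrics: dict) -> list[Path]:
    cohort: Cohort = state["cohort"]
    res = apply_inclusion_filter(cohort.biomarkers, config.abeta_cutoff_pg_ml, config.suvr_cutoff)
    path = out / "inclusion.json"
    payload = {
        "n_included": res.n_included,
        "n_csf": res.n_csf,
        "n_pet_only": res.n_pet_only,
        "excluded": {str(k): v for k, v in res.excluded_reason.items()},
    }
    path.write_text(json.dumps(payload, indent=2))
    metrics["filter"] = {k: payload[k] for k in ["n_included", "n_csf", "n_pet_only"]}
    state["included"] = res.included
    return [path]


def _stage_cluster(config: PipelineConfig, out: Path, state: dict, metrics: dict) -> list[Path]:
    from sklearn.metrics import adjusted_rand_score

    cohort: Cohort = state["cohort"]
    D = pairwise_dtw(cohort.trajectories)
    k_sel, widths = silhouette_select_k(D, config.k_range, config.linkage)
    assignment = hierarchical_cluster(D, config.linkage, k=2)
    assignment = name_phenotypes(assignment, cohort.trajectories)
    phenotypes = assignment.phenotypes
    state["assignment"] = assignment
    state["phenotypes"] = phenotypes

    labels_path = out / "labels.csv"
    pd.DataFrame(
        {"subject_id": cohort.subject_ids, "cluster": assignment.labels, "phenotype": phenotypes}
    ).to_csv(labels_path, index=False)
    nwk_path = out / "dendrogram.nwk"
    nwk_path.write_text(merge_tree_to_newick(assignment.merge_tree, cohort.n_subjects,
                                             cohort.subject_ids))
    sil_path = out / "silhouette.json"
    sil_path.write_text(json.dumps({"selected_k": k_sel, "widths": widths}, indent=2))

    metrics["cluster"] = {
        "selected_k": k_sel,
        "silhouette_widths": widths,
        "ari_vs_truth": float(adjusted_rand_score(cohort.true_class, phenotypes)),
        "n_md": int((phenotypes == "MD").sum()),
        "n_fd": int((phenotypes == "FD").sum()),
    }
    if config.make_figures:
        from .plots import plot_dendrogram, plot_trajectories

        plot_trajectories(cohort.trajectories, phenotypes, out / "trajectories.png")
        plot_dendrogram(assignment.merge_tree, cohort.n_subjects, out / "dendrogram.png")
    return [labels_path, nwk_path, sil_path]


def _stage_stats(config: PipelineConfig, out: Path, state: dict, metrics: dict) -> list[Path]:
    cohort: Cohort = state["cohort"]
    phenotypes = state["phenotypes"]
    seed = stage_seed(config.seed, "stats")

    p_perm, observed, _ = permutation_cluster_test(
        cohort.trajectories, state["assignment"].labels, n_perm=config.n_perm, seed=seed
    )
    anova = rm_anova(cohort.trajectories.scores, phenotypes)
    t_age, p_age = group_difference(cohort.demographics["age"].to_numpy(), phenotypes, "t")
    t_edu, p_edu = group_difference(cohort.demographics["education"].to_numpy(), phenotypes,
                                    "ranksum")
    pos, _ = tau_positive(cohort.biomarkers["ptau"].to_numpy(), config.ptau_cutoff_pg_ml)
    tau_table = pd.crosstab(pos, phenotypes).to_numpy()
    tau_res = chi_square(tau_table)

    payload = {
        "permutation_cluster_test": {"p": p_perm, "statistic": observed, "n_perm": config.n_perm},
        "rm_anova_mmse": dataclasses.asdict(anova),
        "age_t_test": {"stat": t_age, "p": p_age},
        "education_ranksum": {"stat": t_edu, "p": p_edu},
        "tau_positivity_chi2": {
            "table": tau_table.tolist(),
            "chi2": tau_res.chi2,
            "df": tau_res.df,
            "p": tau_res.p,
        },
    }
    path = out / "stats_report.json"
    path.write_text(json.dumps(payload, indent=2, default=float))
    metrics["stats"] = {
        "permutation_p": p_perm,
        "F_time": anova.F_time,
        "F_interaction": anova.F_interaction,
        "tau_chi2": tau_res.chi2,
        "tau_chi2_p": tau_res.p,
    }
    return [path]


def _stage_ablate(config: PipelineConfig, out: Path, state: dict, metrics: dict) -> list[Path]:
    cohort: Cohort = state["cohort"]
    labels = (state["phenotypes"] == "FD").astype(int)
    train_cfg = dataclasses.replace(config.train, seed=stage_seed(config.seed, "ablate"))
    results = run_ablation(cohort, config.combinations, config.spec, train_cfg, labels)
    state["ablation"] = results

    payload = {
        r.combination: {
            "accuracy_mean": r.accuracy_mean,
            "accuracy_sd": r.accuracy_sd,
            "pooled_auc": r.pooled_auc,
            "fold_accuracies": r.fold_accuracies.tolist(),
            "roc": r.roc.tolist(),
        }
        for r in results
    }
    by_combo = {r.combination: r for r in results}
    if "A(N)" in by_combo and "T(N)" in by_combo:
        red = redundancy_analysis(cohort, by_combo["A(N)"].predictions,
                                  by_combo["T(N)"].predictions)
        payload["redundancy"] = {k: {"stat": v[0], "p": v[1]} for k, v in red.items()}
    path = out / "ablation_report.json"
    path.write_text(json.dumps(payload, indent=2, default=float))

    pred_path = out / "predictions.csv"
    pred_df = pd.DataFrame({"subject_id": cohort.subject_ids})
    for r in results:
        pred_df[f"p_fd_{r.combination}"] = r.probabilities
    pred_df.to_csv(pred_path, index=False)

    metrics["ablate"] = {
        r.combination: {"accuracy_mean": r.accuracy_mean, "pooled_auc": r.pooled_auc}
        for r in results
    }
    if config.make_figures:
        from .plots import plot_roc

        plot_roc(results, out / "roc.png")
    return [path, pred_path]


def _stage_subtype(config: PipelineConfig, out: Path, state: dict, metrics: dict) -> list[Path]:
    cohort: Cohort = state["cohort"]
    ratios = compute_ratio(
        cohort.regional_volumes["hippocampal_volume"].to_numpy(),
        cohort.regional_volumes["cortical_total_volume"].to_numpy(),
    )
    assignments = assign_subtypes(ratios, cohort.subject_ids)
    sub_path = out / "subtypes.csv"
    pd.DataFrame(
        {
            "subject_id": [a.subject_id for a in assignments],
            "hv_ctv_ratio": [a.hv_ctv_ratio for a in assignments],
            "subtype": [a.subtype for a in assignments],
        }
    ).to_csv(sub_path, index=False)

    result, table = associate(assignments, state["phenotypes"])
    assoc_path = out / "association_report.json"
    assoc_path.write_text(
        json.dumps(
            {
                "table": table.to_dict(),
                "chi2": result.chi2,
                "df": result.df,
                "p": result.p,
                "thresholds": [assignments[0].threshold_25, assignments[0].threshold_75],
            },
            indent=2,
            default=float,
        )
    )
    counts = {s: int((np.array([a.subtype for a in assignments]) == s).sum())
              for s in ("HpSp", "LP", "tAD")}
    metrics["subtype"] = {"counts": counts, "chi2": result.chi2, "p": result.p}
    return [sub_path, assoc_path]
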