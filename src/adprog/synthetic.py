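"""Synthetic cohort generator for Alzheimer's-continuum progression analyses.

Real studies of progression phenotyping draw on restricted-access cohorts
(longitudinal MMSE, baseline T1 MRI, FDG-PET, CSF Aβ/p-tau).  This module
emulates that data-generating structure so the whole pipeline — trajectory
clustering, multimodal classification, ablation, subtyping — is testable
end to end:

* two latent decline classes, Moderate (MD) and Fast (FD) decliners, with
  class-specific quadratic trajectory models on an MMSE-like 0–30 scale;
* piecewise-constant volume "phantoms": a large cortex-like ellipsoidal
  shell and a small hippocampus-like ellipsoid on a noise background, with
  class-dependent atrophy scaling of both region intensity and size;
* baseline scalar biomarkers (CSF Aβ pg/mL, CSF p-tau pg/mL, FDG composite,
  amyloid-PET SUVR, ICV mm³) drawn per class, plus a label-independent pure
  noise scalar for null-addition experiments;
* an optional label-refinement step that resamples the class from a
  logistic model in standardized A, T, N with an A×T product term, so that
  joint AT(N) information exceeds any marginal subset.

All randomness flows through a single :class:`numpy.random.Generator`
seeded from ``config.seed``, so cohorts are bitwise reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ClassTrajectoryParams",
    "ClassAtrophyParams",
    "BiomarkerParams",
    "CohortConfig",
    "TrajectoryMatrix",
    "Cohort",
    "InclusionResult",
    "generate_cohort",
    "apply_inclusion_filter",
    "write_cohort",
    "load_cohort_tables",
]

# Amyloid-positivity thresholds used for cohort inclusion.
ABETA_CUTOFF_PG_ML = 976.6
SUVR_CUTOFF = 1.11


class ConfigurationError(ValueError):
    """Raised when a cohort configuration is internally inconsistent."""


class CohortSizeError(ValueError):
    """Raised when n_subjects is too small to populate every class."""


@dataclass(frozen=True)
class ClassTrajectoryParams:
    """Quadratic-trend trajectory model for one decline class.

    score(t) = baseline + slope * t + nonlinearity * t^2 + noise,
    with t in years and noise ~ N(0, noise_sd).
    """

    baseline_mean: float
    baseline_sd: float
    slope_mean: float  # score units per year (negative = decline)
    slope_sd: float
    nonlinearity: float  # score units per year^2
    noise_sd: float


@dataclass(frozen=True)
class ClassAtrophyParams:
    """Class-conditional atrophy factor distribution.

    Per-subject multiplicative factors are drawn from clipped normals
    centred on ``hippocampal`` / ``cortical`` (both in (0, 1]); the sds
    control the between-subject overlap of the two classes and hence how
    informative imaging is about the phenotype.  Zero sds give the
    deterministic factors of an idealized noise-free cohort.
    """

    hippocampal: float
    cortical: float
    hippocampal_sd: float = 0.0
    cortical_sd: float = 0.0


@dataclass(frozen=True)
class BiomarkerParams:
    """Mean/sd of baseline scalar biomarkers for one class."""

    abeta_mean: float
    abeta_sd: float
    ptau_mean: float
    ptau_sd: float
    fdg_mean: float
    fdg_sd: float
    suvr_mean: float
    suvr_sd: float
    icv_mean: float
    icv_sd: float


#: Defaults emulate a prodromal/clinical AD continuum: both classes start
#: near the dementia-screen ceiling; FD declines several points per year
#: faster with mild acceleration, consistent with a fast/moderate split of
#: 24-month MMSE bundles.
_DEFAULT_TRAJ = {
    "MD": ClassTrajectoryParams(27.5, 1.2, -1.25, 0.45, 0.0, 0.8),
    "FD": ClassTrajectoryParams(26.5, 1.4, -4.75, 0.75, -0.5, 0.8),
}

_DEFAULT_ATROPHY = {
    "MD": ClassAtrophyParams(hippocampal=0.92, cortical=0.97, hippocampal_sd=0.20, cortical_sd=0.12),
    "FD": ClassAtrophyParams(hippocampal=0.72, cortical=0.90, hippocampal_sd=0.20, cortical_sd=0.12),
}

# Amyloid-positive continuum values: low CSF Aβ, elevated p-tau (higher in
# FD), reduced FDG metabolism in FD, SUVR above the 1.11 positivity line.
_DEFAULT_BIOMARKERS = {
    "MD": BiomarkerParams(700.0, 150.0, 28.0, 8.0, 1.25, 0.10, 1.30, 0.12, 1.5e6, 1.5e5),
    "FD": BiomarkerParams(620.0, 150.0, 38.0, 10.0, 1.10, 0.10, 1.40, 0.12, 1.5e6, 1.5e5),
}


@dataclass(frozen=True)
class CohortConfig:
    """Full description of a synthetic cohort draw."""

    n_subjects: int = 300
    class_proportions: tuple[float, float] = (0.6, 0.4)  # (MD, FD)
    n_timepoints: int = 4
    visit_months: tuple[int, ...] = (0, 6, 12, 24)
    trajectory_params: Mapping[str, ClassTrajectoryParams] = field(
        default_factory=lambda: dict(_DEFAULT_TRAJ)
    )
    volume_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: float = 4.0
    volume_noise_sd: float = 0.10
    atrophy_params: Mapping[str, ClassAtrophyParams] = field(
        default_factory=lambda: dict(_DEFAULT_ATROPHY)
    )
    biomarker_params: Mapping[str, BiomarkerParams] = field(
        default_factory=lambda: dict(_DEFAULT_BIOMARKERS)
    )
    # Label-refinement logistic model (pathology-signed standardized scores).
    synergy_coefficient: float = 0.0
    abeta_effect: float = 0.5
    ptau_effect: float = 1.5
    fdg_effect: float = 0.6
    # Probability of nulling out FDG / SUVR per subject (missing-data knob).
    missing_fdg_prob: float = 0.0
    missing_suvr_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2 * len(self.class_proportions):
            raise CohortSizeError(
                f"n_subjects={self.n_subjects} cannot populate "
                f"{len(self.class_proportions)} classes with >= 2 subjects each"
            )
        props = np.asarray(self.class_proportions, dtype=float)
        if not np.all(np.isfinite(props)) or abs(props.sum() - 1.0) > 1e-12:
            raise ConfigurationError("class_proportions must be finite and sum to 1")
        if self.n_timepoints < 1 or len(self.visit_months) != self.n_timepoints:
            raise ConfigurationError("visit_months length must equal n_timepoints")
        months = np.asarray(self.visit_months, dtype=float)
        if np.any(months < 0) or np.any(np.diff(months) <= 0):
            raise ConfigurationError("visit_months must be non-negative, strictly increasing")
        if any(s < 8 for s in self.volume_shape) or len(self.volume_shape) != 3:
            raise ConfigurationError("volume_shape must be 3 integers, each >= 8")
        for cls, tp in self.trajectory_params.items():
            vals = dataclasses.astuple(tp)
            if not np.all(np.isfinite(vals)):
                raise ConfigurationError(f"non-finite trajectory parameter for class {cls}")
            if tp.baseline_sd < 0 or tp.slope_sd < 0 or tp.noise_sd < 0:
                raise ConfigurationError(f"negative sd in trajectory params for class {cls}")
        for cls, ap in self.atrophy_params.items():
            if not (0 < ap.hippocampal <= 1 and 0 < ap.cortical <= 1):
                raise ConfigurationError(f"atrophy factors for {cls} must lie in (0, 1]")
            if ap.hippocampal_sd < 0 or ap.cortical_sd < 0:
                raise ConfigurationError(f"negative atrophy sd for class {cls}")
        for cls, bp in self.biomarker_params.items():
            vals = np.asarray(dataclasses.astuple(bp))
            if not np.all(np.isfinite(vals)):
                raise ConfigurationError(f"non-finite biomarker parameter for class {cls}")
            if np.any(vals[1::2] < 0):
                raise ConfigurationError(f"negative biomarker sd for class {cls}")

    @property
    def class_names(self) -> tuple[str, ...]:
        return ("MD", "FD")


def default_synergy_config(n_subjects: int = 200, seed: int = 0, **overrides) -> CohortConfig:
    """The default synergy cohort: labels resampled from the logistic
    AT(N) model with an A x T interaction, so joint biomarker information
    exceeds any marginal subset."""
    return CohortConfig(
        n_subjects=n_subjects, synergy_coefficient=2.0, seed=seed, **overrides
    )


@dataclass
class TrajectoryMatrix:
    """Subject x visit cognitive-score matrix (MMSE-like units)."""

    scores: np.ndarray  # (n_subjects, n_timepoints)
    visit_months: np.ndarray  # (n_timepoints,)
    subject_ids: np.ndarray  # (n_subjects,) of str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.visit_months = np.asarray(self.visit_months, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.scores.ndim != 2 or self.scores.shape[1] != self.visit_months.size:
            raise ValueError("scores must be (n_subjects, n_timepoints)")

    @property
    def n_subjects(self) -> int:
        return self.scores.shape[0]

    def to_long(self) -> pd.DataFrame:
        n, t = self.scores.shape
        return pd.DataFrame(
            {
                "subject_id": np.repeat(self.subject_ids, t),
                "month": np.tile(self.visit_months, n),
                "score": self.scores.ravel(),
            }
        )

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "TrajectoryMatrix":
        wide = df.pivot(index="subject_id", columns="month", values="score").sort_index(axis=1)
        return cls(
            scores=wide.to_numpy(dtype=float),
            visit_months=wide.columns.to_numpy(dtype=float),
            subject_ids=wide.index.to_numpy(),
        )


@dataclass
class Cohort:
    """One synthetic cohort: every per-subject container shares ordering."""

    subject_ids: np.ndarray
    true_class: np.ndarray  # "MD" | "FD"
    trajectories: TrajectoryMatrix
    volumes: np.ndarray  # (n, *volume_shape) float32
    voxel_size_mm: float
    biomarkers: pd.DataFrame  # columns abeta, ptau, fdg, suvr, icv, noise
    regional_volumes: pd.DataFrame  # hippocampal_volume, cortical_total_volume (mm³)
    demographics: pd.DataFrame  # age, sex, education
    config: CohortConfig

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        for name, obj in [
            ("true_class", self.true_class),
            ("volumes", self.volumes),
            ("biomarkers", self.biomarkers),
            ("regional_volumes", self.regional_volumes),
            ("demographics", self.demographics),
        ]:
            if len(obj) != n:
                raise ValueError(f"{name} does not match subject count {n}")
        if self.trajectories.n_subjects != n:
            raise ValueError("trajectories do not match subject count")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def labels(self) -> np.ndarray:
        """True class as 0 (MD) / 1 (FD) integers."""
        return (self.true_class == "FD").astype(int)


def _ellipsoid_mask(shape: tuple[int, int, int], center: np.ndarray, radii: np.ndarray,
                    inner_radii: np.ndarray | None = None) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    d2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    mask = d2 <= 1.0
    if inner_radii is not None:
        d2i = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, inner_radii))
        mask &= d2i > 1.0
    return mask


def _subject_volume(shape: tuple[int, int, int], hip_factor: float, cor_factor: float,
                    noise_sd: float, rng: np.random.Generator) -> tuple[np.ndarray, float, float]:
    """Phantom volume plus the nominal region volumes (voxel counts).

    The cortex-like region is an ellipsoidal shell spanning most of the
    field of view; the hippocampus-like region a small off-centre
    ellipsoid.  Atrophy shrinks the region linearly in volume (radii scale
    with the cube root of the factor) and dims its intensity.
    """
    shape_arr = np.asarray(shape, dtype=float)
    center = (shape_arr - 1) / 2.0
    r_scale_c = cor_factor ** (1.0 / 3.0)
    r_scale_h = hip_factor ** (1.0 / 3.0)
    cor_outer = 0.44 * shape_arr * r_scale_c
    cor_inner = 0.30 * shape_arr  # inner ventricle-like cavity, fixed
    hip_center = center + np.array([0.12, -0.10, 0.0]) * shape_arr
    hip_radii = 0.10 * shape_arr * r_scale_h

    vol = rng.normal(0.0, noise_sd, size=shape).astype(np.float32)
    cor_mask = _ellipsoid_mask(shape, center, cor_outer, cor_inner)
    hip_mask = _ellipsoid_mask(shape, hip_center, hip_radii)
    vol[cor_mask] += np.float32(0.8 * cor_factor)
    vol[hip_mask] += np.float32(1.2 * hip_factor)
    return vol, float(hip_mask.sum()), float(cor_mask.sum())


def phantom_region_masks(shape: tuple[int, int, int]) -> dict[str, np.ndarray]:
    """Nominal (atrophy-free) region masks of the phantom geometry."""
    shape_arr = np.asarray(shape, dtype=float)
    center = (shape_arr - 1) / 2.0
    hip_center = center + np.array([0.12, -0.10, 0.0]) * shape_arr
    return {
        "cortex": _ellipsoid_mask(shape, center, 0.44 * shape_arr, 0.30 * shape_arr),
        "hippocampus": _ellipsoid_mask(shape, hip_center, 0.10 * shape_arr),
    }


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw one cohort under ``config``; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    names = config.class_names

    # Deterministic class counts (within +/- 1 subject of the proportions),
    # shuffled so class is not confounded with subject index.
    n_md = int(round(n * config.class_proportions[0]))
    n_md = min(max(n_md, 2), n - 2)
    labels = np.array(["MD"] * n_md + ["FD"] * (n - n_md))
    rng.shuffle(labels)

    # --- scalar biomarkers (class-conditional draws) -----------------
    bio = {}
    for col, (m_attr, s_attr) in {
        "abeta": ("abeta_mean", "abeta_sd"),
        "ptau": ("ptau_mean", "ptau_sd"),
        "fdg": ("fdg_mean", "fdg_sd"),
        "suvr": ("suvr_mean", "suvr_sd"),
        "icv": ("icv_mean", "icv_sd"),
    }.items():
        draws = np.empty(n)
        for cls in names:
            bp = config.biomarker_params[cls]
            mask = labels == cls
            draws[mask] = rng.normal(getattr(bp, m_attr), getattr(bp, s_attr), mask.sum())
        bio[col] = np.maximum(draws, 1e-6)  # concentrations / volumes are positive
    bio["noise"] = rng.normal(0.0, 1.0, n)  # label-independent by construction
    biomarkers = pd.DataFrame(bio)

    # --- optional logistic label refinement (A x T synergy) ----------
    if config.synergy_coefficient != 0.0:
        z = lambda v: (v - v.mean()) / v.std()
        z_a = -z(biomarkers["abeta"].to_numpy())  # low Aβ = more amyloid pathology
        z_t = z(biomarkers["ptau"].to_numpy())
        z_n = -z(biomarkers["fdg"].to_numpy())  # low metabolism = more degeneration
        logit = (
            config.abeta_effect * z_a
            + config.ptau_effect * z_t
            + config.fdg_effect * z_n
            + config.synergy_coefficient * z_a * z_t
        )
        # Intercept chosen so the expected FD fraction matches the request.
        from scipy.optimize import brentq
        from scipy.special import expit

        target = config.class_proportions[1]
        b0 = brentq(lambda b: expit(logit + b).mean() - target, -30, 30)
        p_fd = expit(logit + b0)
        labels = np.where(rng.random(n) < p_fd, "FD", "MD")
        # Guarantee both classes are populated.
        for cls in names:
            if (labels == cls).sum() < 2:
                idx = rng.choice(np.flatnonzero(labels != cls), 2, replace=False)
                labels[idx] = cls

    # --- trajectories (regenerated from final labels) -----------------
    t_years = np.asarray(config.visit_months, dtype=float) / 12.0
    scores = np.empty((n, config.n_timepoints))
    for cls in names:
        tp = config.trajectory_params[cls]
        mask = labels == cls
        m = int(mask.sum())
        base = rng.normal(tp.baseline_mean, tp.baseline_sd, m)[:, None]
        slope = rng.normal(tp.slope_mean, tp.slope_sd, m)[:, None]
        noise = rng.normal(0.0, tp.noise_sd, (m, config.n_timepoints))
        scores[mask] = base + slope * t_years + tp.nonlinearity * t_years**2 + noise

    subject_ids = np.array([f"S{i:04d}" for i in range(n)])
    trajectories = TrajectoryMatrix(scores, np.asarray(config.visit_months, float), subject_ids)

    # --- volumes and regional volumes ---------------------------------
    vox_mm3 = config.voxel_size_mm**3
    volumes = np.empty((n, *config.volume_shape), dtype=np.float32)
    hv = np.empty(n)
    ctv = np.empty(n)
    for i in range(n):
        ap = config.atrophy_params[str(labels[i])]
        f_hip = float(np.clip(rng.normal(ap.hippocampal, ap.hippocampal_sd), 0.25, 1.0))
        f_cor = float(np.clip(rng.normal(ap.cortical, ap.cortical_sd), 0.40, 1.0))
        vol, hip_vox, cor_vox = _subject_volume(
            config.volume_shape, f_hip, f_cor, config.volume_noise_sd, rng
        )
        volumes[i] = vol
        hv[i] = hip_vox * vox_mm3 * rng.lognormal(0.0, 0.05)
        ctv[i] = cor_vox * vox_mm3 * rng.lognormal(0.0, 0.05)
    regional = pd.DataFrame({"hippocampal_volume": hv, "cortical_total_volume": ctv})

    # --- demographics --------------------------------------------------
    demographics = pd.DataFrame(
        {
            "age": rng.normal(73.5, 7.5, n).clip(50, 95),
            "sex": rng.choice(["M", "F"], n),
            "education": rng.normal(16.0, 2.5, n).clip(6, 24).round(),
            "apoe4": rng.binomial(1, 0.5, n),
        }
    )

    # --- optional missingness -----------------------------------------
    if config.missing_fdg_prob > 0:
        biomarkers.loc[rng.random(n) < config.missing_fdg_prob, "fdg"] = np.nan
    if config.missing_suvr_prob > 0:
        biomarkers.loc[rng.random(n) < config.missing_suvr_prob, "suvr"] = np.nan

    return Cohort(
        subject_ids=subject_ids,
        true_class=np.asarray(labels),
        trajectories=trajectories,
        volumes=volumes,
        voxel_size_mm=config.voxel_size_mm,
        biomarkers=biomarkers,
        regional_volumes=regional,
        demographics=demographics,
        config=config,
    )


@dataclass
class InclusionResult:
    """Outcome of the amyloid-positivity inclusion filter."""

    included: np.ndarray  # boolean per subject
    n_csf: int  # qualified via the CSF Aβ criterion (CSF precedence)
    n_pet_only: int  # qualified via SUVR only
    excluded_reason: dict[int, str]

    @property
    def n_included(self) -> int:
        return int(self.included.sum())


def apply_inclusion_filter(
    biomarkers: pd.DataFrame,
    abeta_cutoff: float = ABETA_CUTOFF_PG_ML,
    suvr_cutoff: float = SUVR_CUTOFF,
) -> InclusionResult:
    """Amyloid-positivity inclusion: CSF Aβ < cutoff OR SUVR > cutoff.

    Both inequalities are strict.  When a subject qualifies on both
    measures the CSF criterion takes precedence in the per-criterion
    accounting, so the two counts are disjoint.  Subjects missing both
    measures are excluded with reason "no amyloid measure".
    """
    abeta = biomarkers["abeta"].to_numpy(dtype=float)
    suvr = biomarkers["suvr"].to_numpy(dtype=float)
    csf_ok = np.nan_to_num(abeta, nan=np.inf) < abeta_cutoff
    pet_ok = np.nan_to_num(suvr, nan=-np.inf) > suvr_cutoff
    both_missing = np.isnan(abeta) & np.isnan(suvr)
    if not np.all(~np.isnan(abeta) | ~np.isnan(suvr)):
        pass  # handled below via exclusion reasons
    included = (csf_ok | pet_ok) & ~both_missing
    reasons = {}
    for i in np.flatnonzero(~included):
        reasons[int(i)] = "no amyloid measure" if both_missing[i] else "amyloid negative"
    return InclusionResult(
        included=included,
        n_csf=int(csf_ok.sum()),
        n_pet_only=int((pet_ok & ~csf_ok).sum()),
        excluded_reason=reasons,
    )


# ----------------------------------------------------------------------
# Persistence
# ----------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir: str | Path, write_volumes: bool = True) -> None:
    """Write the cohort as CSV tables + per-subject NIfTI volumes + manifest."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.trajectories.to_long().to_csv(out / "trajectories.csv", index=False)
    bio = cohort.biomarkers.copy()
    bio.insert(0, "subject_id", cohort.subject_ids)
    bio.to_csv(out / "biomarkers.csv", index=False)
    reg = cohort.regional_volumes.copy()
    reg.insert(0, "subject_id", cohort.subject_ids)
    reg.to_csv(out / "regional_volumes.csv", index=False)
    demo = cohort.demographics.copy()
    demo.insert(0, "subject_id", cohort.subject_ids)
    demo.to_csv(out / "demographics.csv", index=False)
    truth = pd.DataFrame({"subject_id": cohort.subject_ids, "true_class": cohort.true_class})
    truth.to_csv(out / "true_class.csv", index=False)

    vol_dir = out / "volumes"
    if write_volumes:
        vol_dir.mkdir(exist_ok=True)
        affine = np.diag([cohort.voxel_size_mm] * 3 + [1.0])  # RAS+, isotropic
        for sid, vol in zip(cohort.subject_ids, cohort.volumes):
            nib.save(nib.Nifti1Image(vol, affine), vol_dir / f"{sid}.nii")

    manifest = {
        "n_subjects": cohort.n_subjects,
        "volume_shape": list(cohort.volumes.shape[1:]),
        "voxel_size_mm": cohort.voxel_size_mm,
        "seed": cohort.config.seed,
        "volumes_written": bool(write_volumes),
        "files": [
            "trajectories.csv",
            "biomarkers.csv",
            "regional_volumes.csv",
            "demographics.csv",
            "true_class.csv",
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_cohort(in_dir: str | Path, config: CohortConfig | None = None) -> Cohort:
    """Reconstruct a Cohort from a directory written by :func:`write_cohort`.

    Volumes are read from the per-subject NIfTI files; a directory
    written with ``write_volumes=False`` cannot back training-stage use.
    """
    import nibabel as nib

    out = Path(in_dir)
    tables = load_cohort_tables(out)
    manifest = json.loads((out / "manifest.json").read_text())
    traj = TrajectoryMatrix.from_long(tables["trajectories"])
    subject_ids = traj.subject_ids
    vol_dir = out / "volumes"
    if not vol_dir.exists():
        raise FileNotFoundError(f"no volumes/ directory under {out}")
    volumes = np.stack(
        [np.asanyarray(nib.load(vol_dir / f"{sid}.nii").dataobj, dtype=np.float32)
         for sid in subject_ids]
    )
    order = {sid: i for i, sid in enumerate(subject_ids)}

    def aligned(df: pd.DataFrame) -> pd.DataFrame:
        return df.set_index("subject_id").loc[subject_ids].reset_index(drop=True)

    return Cohort(
        subject_ids=np.asarray(subject_ids),
        true_class=aligned(tables["true_class"])["true_class"].to_numpy(),
        trajectories=traj,
        volumes=volumes,
        voxel_size_mm=float(manifest["voxel_size_mm"]),
        biomarkers=aligned(tables["biomarkers"]),
        regional_volumes=aligned(tables["regional_volumes"]),
        demographics=aligned(tables["demographics"]),
        config=config or CohortConfig(n_subjects=len(subject_ids), seed=manifest.get("seed", 0)),
    )


def load_cohort_tables(in_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Read back the CSV tables written by :func:`write_cohort`."""
    out = Path(in_dir)
    return {
        name: pd.read_csv(out / f"{name}.csv")
        for name in ["trajectories", "biomarkers", "regional_volumes", "demographics", "true_class"]
    }
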