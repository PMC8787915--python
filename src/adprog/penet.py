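"""Parameter-efficient multimodal classifier (PENet) and its training loop.

The model predicts the Fast-vs-Moderate decliner phenotype from baseline
AT(N) biomarkers: a 3-D volume encoder of 2 convolution blocks (conv +
batch norm + ELU) followed by 3 separable-convolution blocks (depthwise +
pointwise convolution + batch norm + ELU) with strictly increasing filter
counts, fully-connected branches for each scalar biomarker (FDG composite,
CSF Aβ, CSF p-tau, ICV, ...), and a fused fully-connected head emitting
2-class probabilities.  Separable blocks carry far fewer parameters than
full convolutions with the same filter count, which keeps the model
trainable on small cohorts.

Training follows plain SGD with stepwise exponential learning-rate decay
and L2 regularization on the fully-connected weights, inside stratified
k-fold cross-validation.  Augmentation (rotation, translation, flips) is
applied to training folds only; a leakage guard asserts on every fold that
no evaluated subject contributed any tensor to fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from sklearn.model_selection import StratifiedKFold

from . import nn

__all__ = [
    "PENetSpec",
    "AugmentConfig",
    "TrainConfig",
    "FoldResult",
    "CVSummary",
    "PENetModel",
    "build_penet",
    "augment_volume",
    "ScalarTransform",
    "standardize_volumes",
    "standardize_inputs",
    "stratified_folds",
    "assert_no_leakage",
    "train_cv",
    "MODALITY_COMBINATIONS",
]

SCALAR_MODALITIES = ("fdg", "abeta", "ptau", "icv", "noise")

#: Biomarker-combination labels used in the ablation experiments.
MODALITY_COMBINATIONS: dict[str, tuple[str, ...]] = {
    "MRI-only": ("mri",),
    "N": ("mri", "fdg"),
    "A(N)": ("mri", "fdg", "abeta"),
    "T(N)": ("mri", "fdg", "ptau"),
    "AT(N)": ("mri", "fdg", "abeta", "ptau"),
    "N+ICV": ("mri", "fdg", "icv"),
    "N+noise": ("mri", "fdg", "noise"),
}


class LeakageError(AssertionError):
    """A test-fold subject contributed data to model fitting."""


class ModalityError(ValueError):
    """A modality enabled in the spec is absent from the data."""


@dataclass(frozen=True)
class PENetSpec:
    """Architecture description.  Defaults fit 32-voxel-cube inputs."""

    conv_blocks: tuple[tuple[int, int, int], ...] = ((8, 3, 2), (16, 3, 2))
    sepconv_blocks: tuple[tuple[int, int, int], ...] = ((32, 3, 2), (64, 3, 2), (128, 3, 2))
    scalar_branch_widths: tuple[int, ...] = (8, 8)
    fusion_widths: tuple[int, ...] = (32, 16)
    dropout_rate: float = 0.0
    input_volume_shape: tuple[int, int, int] = (32, 32, 32)
    enabled_modalities: tuple[str, ...] = ("mri", "fdg", "abeta", "ptau")

    def __post_init__(self) -> None:
        filters = [f for f, _, _ in self.conv_blocks + self.sepconv_blocks]
        if any(b <= a for a, b in zip(filters, filters[1:])):
            raise ValueError("filter counts must be strictly increasing across blocks")
        if "mri" not in self.enabled_modalities:
            raise ValueError("the volume branch (mri) is required")
        for m in self.enabled_modalities:
            if m != "mri" and m not in SCALAR_MODALITIES:
                raise ValueError(f"unknown modality {m!r}")

    @property
    def scalar_modalities(self) -> tuple[str, ...]:
        return tuple(m for m in self.enabled_modalities if m != "mri")


@dataclass(frozen=True)
class AugmentConfig:
    """Stochastic augmentation settings (training folds only).

    Rotation angle ~ U(-rotation_deg, rotation_deg) in the axial plane;
    translation by a fraction ~ U(0, shift_frac) of each dimension with a
    random sign; flips along ``flip_axes`` with probability 1/2 each.
    """

    rotation_deg: float = 90.0
    shift_frac: float = 0.5
    flip_axes: tuple[int, ...] = (0,)
    copies: int = 4  # augmented copies per training subject

    def __post_init__(self) -> None:
        if not 0 <= self.rotation_deg <= 90:
            raise ValueError("rotation_deg must lie in [0, 90]")
        if not 0 <= self.shift_frac <= 0.5:
            raise ValueError("shift_frac must lie in [0, 0.5]")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 25
    epochs: int = 50
    initial_lr: float = 8e-4
    lr_drop: float = 0.5
    lr_drop_period: int = 10  # epochs per 0.5 drop
    l2_fc: float = 5e-4
    folds: int = 5
    augmentation: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1 or self.initial_lr <= 0:
            raise ValueError("batch_size, epochs >= 1 and initial_lr > 0 required")


@dataclass
class FoldResult:
    fold: int
    test_indices: np.ndarray
    probabilities: np.ndarray  # P(FD) per held-out subject
    accuracy: float
    auc: float
    confusion: np.ndarray  # [[TN, FP], [FN, TP]]

    def __post_init__(self) -> None:
        if np.any(self.probabilities < 0) or np.any(self.probabilities > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if int(self.confusion.sum()) != len(self.test_indices):
            raise ValueError("confusion counts must sum to fold size")


@dataclass
class CVSummary:
    accuracy_mean: float
    accuracy_sd: float
    pooled_auc: float
    pooled_probabilities: np.ndarray  # out-of-fold P(FD), cohort order
    pooled_predictions: np.ndarray  # out-of-fold hard labels


class PENetModel:
    """Volume encoder + scalar branches + fusion head, with backprop."""

    def __init__(self, spec: PENetSpec, seed: int = 0, dtype=np.float32) -> None:
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)

        vol_layers: list[nn.Layer] = []
        c_prev = 1
        for bi, (f, k, s) in enumerate(spec.conv_blocks):
            vol_layers += [
                nn.Conv3d(c_prev, f, k, s, rng=rng, dtype=dtype, input_layer=(bi == 0)),
                nn.BatchNorm(f, dtype=dtype),
                nn.ELU(),
            ]
            c_prev = f
        for f, k, s in spec.sepconv_blocks:
            vol_layers += [
                nn.DepthwiseConv3d(c_prev, k, s, rng=rng, dtype=dtype),
                nn.Conv3d(c_prev, f, kernel=1, stride=1, rng=rng, dtype=dtype),
                nn.BatchNorm(f, dtype=dtype),
                nn.ELU(),
            ]
            c_prev = f
        vol_layers.append(nn.Flatten())
        self.volume_net = nn.Sequential(*vol_layers)

        # probe the flattened feature size
        probe = np.zeros((1, 1, *spec.input_volume_shape), dtype=dtype)
        vol_feat = self.volume_net.forward(probe).shape[1]

        self.branches: dict[str, nn.Sequential] = {}
        branch_out = 0
        for mod in spec.scalar_modalities:
            layers: list[nn.Layer] = []
            w_prev = 1
            for w in spec.scalar_branch_widths:
                layers += [nn.Dense(w_prev, w, rng=rng, decay=True, dtype=dtype), nn.ELU()]
                w_prev = w
            self.branches[mod] = nn.Sequential(*layers)
            branch_out += w_prev

        fusion_layers: list[nn.Layer] = []
        w_prev = vol_feat + branch_out
        for w in spec.fusion_widths:
            fusion_layers += [nn.Dense(w_prev, w, rng=rng, decay=True, dtype=dtype), nn.ELU()]
            if spec.dropout_rate > 0:
                fusion_layers.append(nn.Dropout(spec.dropout_rate, rng=np.random.default_rng(rng.integers(2**31))))
            w_prev = w
        fusion_layers.append(nn.Dense(w_prev, 2, rng=rng, decay=True, dtype=dtype))
        self.fusion = nn.Sequential(*fusion_layers)
        self._vol_feat = vol_feat

    # -- parameter plumbing -------------------------------------------
    def params(self) -> list[nn.Param]:
        ps = self.volume_net.params()
        for mod in self.spec.scalar_modalities:
            ps += self.branches[mod].params()
        return ps + self.fusion.params()

    @property
    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())

    # -- forward / backward -------------------------------------------
    def forward(self, volumes: np.ndarray, scalars: Mapping[str, np.ndarray],
                training: bool = False) -> np.ndarray:
        for mod in self.spec.scalar_modalities:
            if mod not in scalars:
                raise ModalityError(f"modality {mod!r} enabled but absent from data")
        x = volumes.astype(self.dtype, copy=False)
        if x.ndim == 4:
            x = x[:, None]
        feats = [self.volume_net.forward(x, training)]
        for mod in self.spec.scalar_modalities:
            s = np.asarray(scalars[mod], dtype=self.dtype).reshape(-1, 1)
            feats.append(self.branches[mod].forward(s, training))
        self._split = np.cumsum([f.shape[1] for f in feats])[:-1]
        fused = np.concatenate(feats, axis=1)
        return self.fusion.forward(fused, training)

    def backward(self, dlogits: np.ndarray) -> None:
        dfused = self.fusion.backward(dlogits.astype(self.dtype, copy=False))
        parts = np.split(dfused, self._split, axis=1)
        self.volume_net.backward(parts[0])
        for mod, g in zip(self.spec.scalar_modalities, parts[1:]):
            self.branches[mod].backward(g)

    def predict_proba(self, volumes, scalars) -> np.ndarray:
        logits = self.forward(volumes, scalars, training=False)
        return nn.softmax(logits.astype(np.float64))


def build_penet(spec: PENetSpec, seed: int = 0, dtype=np.float32) -> PENetModel:
    """Construct a PENet with seeded initialization."""
    return PENetModel(spec, seed=seed, dtype=dtype)


def save_checkpoint(model: PENetModel, path) -> None:
    """Persist learned parameters (.npz) with a JSON sidecar of the spec."""
    import dataclasses
    import json
    from pathlib import Path

    path = Path(path)
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    np.savez(path, **arrays)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(dataclasses.asdict(model.spec), indent=2))


def load_checkpoint(path) -> PENetModel:
    """Rebuild a PENet from a checkpoint written by :func:`save_checkpoint`."""
    import json
    from pathlib import Path

    path = Path(path)
    spec_dict = json.loads(path.with_suffix(".json").read_text())
    for key in ("conv_blocks", "sepconv_blocks"):
        spec_dict[key] = tuple(tuple(b) for b in spec_dict[key])
    for key in ("scalar_branch_widths", "fusion_widths", "input_volume_shape",
                "enabled_modalities"):
        spec_dict[key] = tuple(spec_dict[key])
    model = PENetModel(PENetSpec(**spec_dict))
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"p{i}"]
    return model


# ----------------------------------------------------------------------
# Parameter arithmetic (closed forms used by tests and docs)
# ----------------------------------------------------------------------

def conv_block_param_count(c_in: int, filters: int, kernel: int) -> int:
    """conv (c_in*k^3*f + f) + batch norm (2f)."""
    return c_in * kernel**3 * filters + filters + 2 * filters


def sepconv_block_param_count(c_in: int, filters: int, kernel: int) -> int:
    """depthwise (c_in*k^3 + c_in) + pointwise (c_in*f + f) + batch norm (2f)."""
    return c_in * kernel**3 + c_in + c_in * filters + filters + 2 * filters


def scalar_branch_param_count(widths: Sequence[int]) -> int:
    total, w_prev = 0, 1
    for w in widths:
        total += w_prev * w + w
        w_prev = w
    return total


# ----------------------------------------------------------------------
# Augmentation and standardization
# ----------------------------------------------------------------------

def augment_volume(volume: np.ndarray, settings: AugmentConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """One stochastic augmentation of a 3-D volume (shape-preserving).

    Rotation and translation fill exposed voxels with the background value
    0; zero-parameter draws are skipped so the identity case is bitwise.
    """
    if volume.ndim != 3:
        raise ValueError("augment_volume expects a 3-D volume")
    out = volume
    if settings.rotation_deg > 0:
        if volume.shape[0] == 1 or volume.shape[1] == 1:
            raise ValueError("cannot rotate about a degenerate (size-1) axis")
        angle = rng.uniform(-settings.rotation_deg, settings.rotation_deg)
        if angle != 0.0:
            out = ndimage.rotate(out, angle, axes=(0, 1), reshape=False,
                                 order=1, mode="constant", cval=0.0)
    if settings.shift_frac > 0:
        frac = rng.uniform(0.0, settings.shift_frac)
        direction = rng.standard_normal(3)
        direction /= max(np.linalg.norm(direction), 1e-12)
        shift = frac * np.asarray(out.shape) * direction
        if np.any(shift != 0.0):
            out = ndimage.shift(out, shift, order=1, mode="constant", cval=0.0)
    for ax in settings.flip_axes:
        if rng.random() < 0.5:
            out = np.flip(out, axis=ax)
    return np.ascontiguousarray(out, dtype=volume.dtype)


@dataclass
class ScalarTransform:
    """Per-feature z-scoring transform fitted on training-fold statistics."""

    mean_: np.ndarray
    sd_: np.ndarray
    feature_names: tuple[str, ...] = ()
    dropped: tuple[str, ...] = ()

    @classmethod
    def fit(cls, X: np.ndarray, feature_names=()) -> "ScalarTransform":
        X = np.asarray(X, dtype=float)
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        dropped = tuple(
            str(feature_names[j]) if len(feature_names) else str(j)
            for j in np.flatnonzero(sd == 0)
        )
        if dropped:
            import warnings

            warnings.warn(f"zero-variance features dropped from scaling: {dropped}")
        sd = np.where(sd == 0, 1.0, sd)
        return cls(mean_=mean, sd_=sd, feature_names=tuple(feature_names), dropped=dropped)

    def apply(self, X) -> "StandardizedScalars":
        if isinstance(X, StandardizedScalars):
            raise ValueError("transform already applied (transform-applied flag set)")
        return StandardizedScalars((np.asarray(X, dtype=float) - self.mean_) / self.sd_, self)


@dataclass
class StandardizedScalars:
    values: np.ndarray
    transform: ScalarTransform


def standardize_volumes(volumes: np.ndarray) -> np.ndarray:
    """Per-image z-scoring: each volume to mean 0, unit sd."""
    v = np.asarray(volumes, dtype=np.float32)
    axes = tuple(range(1, v.ndim))
    mean = v.mean(axis=axes, keepdims=True)
    sd = v.std(axis=axes, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("degenerate (constant) volume cannot be standardized")
    return (v - mean) / sd


def standardize_inputs(train_scalars: np.ndarray, apply_scalars: np.ndarray,
                       feature_names=()) -> tuple[StandardizedScalars, StandardizedScalars, ScalarTransform]:
    """Fit scalar z-scoring on the training fold and apply to both sets."""
    tf = ScalarTransform.fit(train_scalars, feature_names)
    return tf.apply(train_scalars), tf.apply(apply_scalars), tf


# ----------------------------------------------------------------------
# Cross-validation
# ----------------------------------------------------------------------

def stratified_folds(labels: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """k disjoint test-index sets, stratified by class, deterministic."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class ({counts.min()}) is below k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


def assert_no_leakage(train_ids: Sequence, test_ids: Sequence) -> None:
    """Raise LeakageError if any subject id appears on both sides."""
    overlap = set(map(str, train_ids)) & set(map(str, test_ids))
    if overlap:
        raise LeakageError(f"subjects in both train and test: {sorted(overlap)[:5]}")


def _resample_volume(vol: np.ndarray, target: tuple[int, int, int]) -> np.ndarray:
    if tuple(vol.shape) == tuple(target):
        return vol
    factors = [t / s for t, s in zip(target, vol.shape)]
    return ndimage.zoom(vol, factors, order=1).astype(vol.dtype)


def train_cv(
    cohort,
    spec: PENetSpec,
    config: TrainConfig,
    labels: np.ndarray | None = None,
    folds: list[np.ndarray] | None = None,
) -> tuple[list[FoldResult], CVSummary]:
    """Stratified cross-validated training of PENet on a cohort.

    ``labels`` defaults to the cohort's true classes (0 = MD, 1 = FD);
    the pipeline passes cluster-derived phenotypes instead.  ``folds``
    may be supplied to share an identical paired split across biomarker
    combinations.
    """
    from .ablation import auc as _auc  # local import to avoid a cycle

    labels = cohort.labels if labels is None else np.asarray(labels, dtype=int)
    n = len(labels)
    if folds is None:
        folds = stratified_folds(labels, config.folds, config.seed)

    scalar_cols = list(spec.scalar_modalities)
    scalars_all = (
        cohort.biomarkers[scalar_cols].to_numpy(dtype=float)
        if scalar_cols
        else np.zeros((n, 0))
    )
    if scalar_cols and np.any(np.isnan(scalars_all)):
        raise ModalityError(f"NaN values in enabled scalar modalities {scalar_cols}")

    vols = cohort.volumes
    if tuple(vols.shape[1:]) != tuple(spec.input_volume_shape):
        vols = np.stack([_resample_volume(v, spec.input_volume_shape) for v in vols])

    subject_ids = np.asarray(cohort.subject_ids)
    fold_results: list[FoldResult] = []
    pooled_probs = np.full(n, np.nan)

    for f_idx, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        rng = np.random.default_rng([config.seed, f_idx])

        # -- augmentation: training subjects only ----------------------
        aug = config.augmentation
        aug_vols = [vols[train_idx]]
        aug_ids = [train_idx]
        for _ in range(aug.copies):
            aug_vols.append(
                np.stack([augment_volume(vols[i], aug, rng) for i in train_idx])
            )
            aug_ids.append(train_idx)
        train_vols_raw = np.concatenate(aug_vols)
        train_rows = np.concatenate(aug_ids)

        assert_no_leakage(subject_ids[train_rows], subject_ids[test_idx])

        train_vols = standardize_volumes(train_vols_raw)
        test_vols = standardize_volumes(vols[test_idx])
        if scalar_cols:
            tr_s, te_s, _ = standardize_inputs(
                scalars_all[train_idx], scalars_all[test_idx], scalar_cols
            )
            # augmented copies reuse their subject's scalar row
            pos_in_train = {int(i): j for j, i in enumerate(train_idx)}
            tr_rows = np.array([pos_in_train[int(i)] for i in train_rows])
            train_scalars = {c: tr_s.values[tr_rows, j] for j, c in enumerate(scalar_cols)}
            test_scalars = {c: te_s.values[:, j] for j, c in enumerate(scalar_cols)}
        else:
            train_scalars, test_scalars = {}, {}
        y_train = labels[train_rows]

        # -- training ---------------------------------------------------
        model = build_penet(spec, seed=int(rng.integers(2**31)))
        opt = nn.SGD(
            model.params(),
            lr=config.initial_lr,
            weight_decay=config.l2_fc,
            lr_drop=config.lr_drop,
            drop_period=config.lr_drop_period,
        )
        m = len(y_train)
        for epoch in range(config.epochs):
            opt.set_epoch(epoch)
            order = rng.permutation(m)
            for start in range(0, m, config.batch_size):
                idx = order[start : start + config.batch_size]
                opt.zero_grad()
                logits = model.forward(
                    train_vols[idx], {c: train_scalars[c][idx] for c in scalar_cols},
                    training=True,
                )
                loss, dlogits, _ = nn.softmax_cross_entropy(logits, y_train[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"divergent loss at epoch {epoch} (lr={opt.lr}, seed={config.seed})"
                    )
                model.backward(dlogits)
                opt.step()

        # -- evaluation on the untouched fold ---------------------------
        probs = model.predict_proba(test_vols, test_scalars)[:, 1]
        pred = (probs >= 0.5).astype(int)
        y_test = labels[test_idx]
        acc = float((pred == y_test).mean())
        cm = np.array(
            [
                [(pred[y_test == 0] == 0).sum(), (pred[y_test == 0] == 1).sum()],
                [(pred[y_test == 1] == 0).sum(), (pred[y_test == 1] == 1).sum()],
            ]
        )
        fold_auc = _auc(probs, y_test) if len(np.unique(y_test)) == 2 else np.nan
        fold_results.append(
            FoldResult(f_idx, np.asarray(test_idx), probs, acc, float(fold_auc), cm)
        )
        pooled_probs[test_idx] = probs

    accs = np.array([fr.accuracy for fr in fold_results])
    pooled_auc = _auc(pooled_probs, labels)
    summary = CVSummary(
        accuracy_mean=float(accs.mean()),
        accuracy_sd=float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
        pooled_auc=float(pooled_auc),
        pooled_probabilities=pooled_probs,
        pooled_predictions=(pooled_probs >= 0.5).astype(int),
    )
    return fold_results, summary
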