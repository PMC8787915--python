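"""Augmentation, standardization, fold stratification, and training loop."""

import numpy as np
import pytest

from adprog.penet import (
    AugmentConfig,
    LeakageError,
    PENetSpec,
    ScalarTransform,
    TrainConfig,
    assert_no_leakage,
    augment_volume,
    standardize_inputs,
    standardize_volumes,
    stratified_folds,
    train_cv,
)
from adprog.synthetic import CohortConfig, generate_cohort

DESK_AUG = AugmentConfig(rotation_deg=15, shift_frac=0.05, copies=1)


class TestAugmentVolume:
    def test_zero_settings_identity_bitwise(self, rng):
        vol = rng.normal(size=(8, 8, 8)).astype(np.float32)
        out = augment_volume(vol, AugmentConfig(rotation_deg=0, shift_frac=0, flip_axes=()),
                             np.random.default_rng(0))
        assert np.array_equal(out, vol)

    def test_double_flip_is_identity(self, rng):
        vol = rng.normal(size=(8, 8, 8)).astype(np.float32)
        assert np.array_equal(np.flip(np.flip(vol, 0), 0), vol)
        # flips drawn with p=1/2: find a seed that flips, apply twice
        cfg = AugmentConfig(rotation_deg=0, shift_frac=0, flip_axes=(0,))
        g = np.random.default_rng(1)
        once = augment_volume(vol, cfg, np.random.default_rng(1))
        twice = augment_volume(once, cfg, np.random.default_rng(1))
        assert np.array_equal(twice, vol)

    def test_shape_preserved(self, rng):
        vol = rng.normal(size=(10, 12, 8)).astype(np.float32)
        out = augment_volume(vol, AugmentConfig(rotation_deg=45, shift_frac=0.3), rng)
        assert out.shape == vol.shape

    def test_small_shift_preserves_mean_intensity(self):
        """Background-padding sanity on a generated phantom."""
        cohort = generate_cohort(CohortConfig(n_subjects=6, volume_shape=(16, 16, 16), seed=0))
        vol = cohort.volumes[0]
        cfg = AugmentConfig(rotation_deg=0, shift_frac=0.1, flip_axes=())
        for seed in range(5):
            out = augment_volume(vol, cfg, np.random.default_rng(seed))
            assert abs(out.mean() - vol.mean()) <= 0.05 * abs(vol.mean())

    def test_degenerate_axis_rotation_rejected(self):
        with pytest.raises(ValueError):
            augment_volume(np.zeros((1, 8, 8)), AugmentConfig(rotation_deg=30),
                           np.random.default_rng(0))

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            AugmentConfig(rotation_deg=120)
        with pytest.raises(ValueError):
            AugmentConfig(shift_frac=0.9)


class TestStandardization:
    def test_training_features_zero_mean_unit_sd(self, rng):
        X = rng.normal(5, 3, size=(50, 4))
        tr, te, _ = standardize_inputs(X, X[:10])
        assert np.allclose(tr.values.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(tr.values.std(axis=0), 1, atol=1e-10)

    def test_applying_transform_twice_guarded(self, rng):
        X = rng.normal(size=(20, 3))
        tf = ScalarTransform.fit(X)
        once = tf.apply(X)
        with pytest.raises(ValueError):
            tf.apply(once)

    def test_test_fold_not_recentred(self, rng):
        """Leakage guard: held-out features keep a nonzero mean under the
        training-fold transform."""
        X_train = rng.normal(0, 1, size=(100, 2))
        X_test = rng.normal(2, 1, size=(40, 2))
        _, te, _ = standardize_inputs(X_train, X_test)
        assert np.all(np.abs(te.values.mean(axis=0)) > 0.5)

    def test_zero_variance_feature_dropped_with_warning(self, rng):
        X = np.column_stack([rng.normal(size=20), np.full(20, 7.0)])
        with pytest.warns(UserWarning):
            tf = ScalarTransform.fit(X, ("a", "b"))
        assert tf.dropped == ("b",)

    def test_volume_standardization_per_image(self, rng):
        vols = rng.normal(3, 2, size=(5, 8, 8, 8))
        out = standardize_volumes(vols)
        assert np.allclose(out.mean(axis=(1, 2, 3)), 0, atol=1e-5)
        assert np.allclose(out.std(axis=(1, 2, 3)), 1, atol=1e-5)


class TestStratifiedFolds:
    def test_divisible_case_exact_balance(self):
        labels = np.r_[np.zeros(60), np.ones(40)].astype(int)
        folds = stratified_folds(labels, 5, seed=0)
        for f in folds:
            assert (labels[f] == 0).sum() == 12
            assert (labels[f] == 1).sum() == 8

    def test_uneven_case_within_one(self):
        labels = np.r_[np.zeros(58), np.ones(39)].astype(int)
        folds = stratified_folds(labels, 5, seed=1)
        for f in folds:
            assert abs((labels[f] == 0).sum() - 58 / 5) <= 1
            assert abs((labels[f] == 1).sum() - 39 / 5) <= 1

    def test_partition_property(self, rng):
        labels = rng.integers(0, 2, 37)
        while min(np.bincount(labels)) < 4:
            labels = rng.integers(0, 2, 37)
        folds = stratified_folds(labels, 4, seed=2)
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(37))

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds(np.r_[np.zeros(20), np.ones(3)].astype(int), 5, seed=0)

    def test_deterministic(self):
        labels = np.r_[np.zeros(30), np.ones(20)].astype(int)
        f1 = stratified_folds(labels, 5, seed=3)
        f2 = stratified_folds(labels, 5, seed=3)
        assert all(np.array_equal(a, b) for a, b in zip(f1, f2))


class TestLeakageGuard:
    def test_disjoint_ok(self):
        assert_no_leakage(["a", "b"], ["c", "d"])

    def test_duplicated_test_subject_caught(self):
        """Adversarial duplication of a held-out subject into training."""
        with pytest.raises(LeakageError):
            assert_no_leakage(["a", "b", "c"], ["c", "d"])


@pytest.fixture(scope="module")
def strong_cohort():
    """Noise-free class-separable volumes (atrophy factor 0.5)."""
    from adprog.synthetic import ClassAtrophyParams

    return generate_cohort(
        CohortConfig(
            n_subjects=60,
            volume_shape=(16, 16, 16),
            volume_noise_sd=0.02,
            atrophy_params={
                "MD": ClassAtrophyParams(1.0, 1.0),
                "FD": ClassAtrophyParams(0.5, 0.5),
            },
            seed=4,
        )
    )


class TestTrainCV:
    def _config(self, seed=0, epochs=4):
        return TrainConfig(batch_size=16, epochs=epochs, initial_lr=0.02,
                           lr_drop_period=2, folds=3, augmentation=DESK_AUG, seed=seed)

    def test_strong_signal_high_accuracy(self, strong_cohort):
        spec = PENetSpec(input_volume_shape=(16, 16, 16), enabled_modalities=("mri", "fdg"))
        _, summary = train_cv(strong_cohort, spec, self._config(epochs=6))
        assert summary.accuracy_mean >= 0.95

    def test_null_signal_near_majority_rate(self):
        """Labels independent of inputs: accuracy within the binomial CI
        of the majority-class rate."""
        cohort = generate_cohort(CohortConfig(n_subjects=60, volume_shape=(12, 12, 12), seed=8))
        rng = np.random.default_rng(0)
        labels = rng.permutation(np.r_[np.zeros(36), np.ones(24)].astype(int))
        spec = PENetSpec(input_volume_shape=(12, 12, 12), enabled_modalities=("mri", "fdg"))
        _, summary = train_cv(cohort, spec, self._config(), labels=labels)
        majority = 36 / 60
        half_width = 1.96 * np.sqrt(majority * (1 - majority) / 60)
        assert summary.accuracy_mean <= majority + half_width + 0.05

    def test_same_seed_reproducible(self, strong_cohort):
        spec = PENetSpec(input_volume_shape=(16, 16, 16), enabled_modalities=("mri", "fdg"))
        _, s1 = train_cv(strong_cohort, spec, self._config(epochs=2))
        _, s2 = train_cv(strong_cohort, spec, self._config(epochs=2))
        assert s1.accuracy_mean == s2.accuracy_mean
        assert np.array_equal(s1.pooled_probabilities, s2.pooled_probabilities)

    def test_fold_confusion_counts_sum(self, strong_cohort):
        spec = PENetSpec(input_volume_shape=(16, 16, 16), enabled_modalities=("mri", "fdg"))
        fold_results, _ = train_cv(strong_cohort, spec, self._config(epochs=2))
        for fr in fold_results:
            assert fr.confusion.sum() == len(fr.test_indices)
            assert np.all((fr.probabilities >= 0) & (fr.probabilities <= 1))

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        from adprog.penet import build_penet, load_checkpoint, save_checkpoint

        spec = PENetSpec(input_volume_shape=(12, 12, 12),
                         enabled_modalities=("mri", "fdg", "ptau"))
        model = build_penet(spec, seed=3)
        vols = rng.normal(size=(3, 12, 12, 12)).astype(np.float32)
        scalars = {m: rng.normal(size=3).astype(np.float32) for m in ("fdg", "ptau")}
        before = model.predict_proba(vols, scalars)
        save_checkpoint(model, tmp_path / "model.npz")
        restored = load_checkpoint(tmp_path / "model.npz")
        after = restored.predict_proba(vols, scalars)
        assert np.allclose(before, after, atol=1e-6)
        assert restored.spec == spec

    def test_missing_modality_rejected(self, strong_cohort):
        from adprog.penet import ModalityError

        bad = strong_cohort.biomarkers.copy()
        bad["fdg"] = np.nan
        import dataclasses as dc

        cohort = dc.replace(strong_cohort, biomarkers=bad)
        spec = PENetSpec(input_volume_shape=(16, 16, 16), enabled_modalities=("mri", "fdg"))
        with pytest.raises(ModalityError):
            train_cv(cohort, spec, self._config(epochs=1))
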