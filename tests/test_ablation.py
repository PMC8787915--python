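"""ROC/AUC statistics, DeLong test, baselines, and harness contracts."""

import numpy as np
import pytest

from adprog.ablation import (
    auc,
    delong_test,
    delong_variance,
    redundancy_analysis,
    roc_points,
    run_ablation,
    scalar_baseline,
)
from adprog.penet import AugmentConfig, PENetSpec, TrainConfig, stratified_folds
from adprog.stats import DegenerateDataError


class TestAuc:
    def test_pair_counting_example(self):
        # 3 of 4 pos-neg pairs correctly ordered
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_half(self):
        assert auc([0.5] * 8, [0, 0, 0, 0, 1, 1, 1, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    def test_trapezoid_identity_random_scores(self, rng):
        """ROC trapezoid integral equals the Mann-Whitney form exactly."""
        for _ in range(100):
            n = int(rng.integers(10, 60))
            labels = np.r_[0, 1, rng.integers(0, 2, n)]
            scores = rng.normal(size=n + 2).round(1)  # ties included
            pts = roc_points(scores, labels)
            trap = np.trapezoid(pts[:, 1], pts[:, 0])
            assert abs(trap - auc(scores, labels)) < 1e-12

    def test_roc_endpoints_and_monotonicity(self, rng):
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        pts = roc_points(rng.normal(size=40), labels)
        assert np.allclose(pts[0], [0, 0]) and np.allclose(pts[-1], [1, 1])
        assert np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)


class TestDeLong:
    def test_identical_scores_z_zero(self, rng):
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        s = rng.normal(size=30)
        z, p, d = delong_test(s, s, labels=y)
        assert z == 0.0 and p == 1.0 and d == 0.0

    def test_null_p_values_uniform(self, rng):
        """Single-model test on label-independent scores: p ~ U(0,1)."""
        from scipy import stats as sps

        ps = []
        for _ in range(200):
            y = rng.integers(0, 2, 400)
            if y.sum() in (0, 400):
                continue
            _, p, _ = delong_test(rng.normal(size=400), labels=y)
            ps.append(p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_variance_matches_bootstrap(self, rng):
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        s = rng.normal(size=40)
        v = delong_variance(s, y)
        boots = []
        for _ in range(10000):
            idx = rng.integers(0, 40, 40)
            if len(np.unique(y[idx])) == 2:
                boots.append(auc(s[idx], y[idx]))
        assert abs(v - np.var(boots)) / np.var(boots) < 0.10

    def test_z_squared_close_to_mann_whitney(self, rng):
        """Single-model DeLong z agrees with the normal-approximation
        Mann-Whitney z on two-distinct-score data."""
        from scipy import stats as sps

        y = np.r_[np.zeros(40), np.ones(40)].astype(int)
        s = np.r_[rng.normal(0, 1, 40), rng.normal(0.8, 1, 40)]
        z, _, _ = delong_test(s, labels=y)
        u = sps.mannwhitneyu(s[y == 1], s[y == 0], alternative="two-sided",
                             method="asymptotic")
        z_mw = sps.norm.isf(u.pvalue / 2)
        assert abs(z**2 - z_mw**2) / z_mw**2 < 0.25

    def test_unpaired_rejected(self, rng):
        with pytest.raises(ValueError):
            delong_test(rng.normal(size=10), rng.normal(size=12),
                        labels=np.r_[np.zeros(5), np.ones(5)])


class TestScalarBaseline:
    def test_label_identical_feature_perfect(self):
        y = np.r_[np.zeros(30), np.ones(30)].astype(int)
        acc, _, _ = scalar_baseline(y.astype(float), y, "logistic", n_folds=5, seed=0)
        assert acc == 1.0

    def test_noise_feature_near_majority(self, rng):
        y = np.r_[np.zeros(60), np.ones(40)].astype(int)
        acc, _, _ = scalar_baseline(rng.normal(size=100), y, "logistic", n_folds=5, seed=0)
        assert acc <= 0.6 + 1.96 * np.sqrt(0.6 * 0.4 / 100) + 0.05

    def test_svm_runs_and_scores(self, rng):
        y = np.r_[np.zeros(30), np.ones(30)].astype(int)
        X = np.column_stack([rng.normal(2.0 * y, 0.5), rng.normal(size=60)])
        acc, sd, scores = scalar_baseline(X, y, "svm_rbf", n_folds=3, seed=0)
        assert acc > 0.85
        assert not np.isnan(scores).any()

    def test_constant_feature_dropped(self, rng):
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        X = np.column_stack([y + rng.normal(0, 0.1, 40), np.full(40, 3.0)])
        with pytest.warns(UserWarning):
            acc, _, _ = scalar_baseline(X, y, "logistic", n_folds=4, seed=0)
        assert acc > 0.9


@pytest.fixture(scope="module")
def tiny_setup():
    from adprog.synthetic import default_synergy_config, generate_cohort

    cohort = generate_cohort(default_synergy_config(48, seed=5, volume_shape=(12, 12, 12)))
    spec = PENetSpec(input_volume_shape=(12, 12, 12))
    cfg = TrainConfig(batch_size=16, epochs=2, initial_lr=0.02, folds=3,
                      augmentation=AugmentConfig(rotation_deg=10, shift_frac=0.05, copies=1),
                      seed=0)
    return cohort, spec, cfg


class TestHarness:
    def test_fold_sets_identical_across_combinations(self, tiny_setup):
        cohort, spec, cfg = tiny_setup
        folds = stratified_folds(cohort.labels, cfg.folds, cfg.seed)
        results = run_ablation(cohort, ["N", "T(N)"], spec, cfg)
        for r in results:
            assert not np.isnan(r.probabilities).any()  # every subject scored once
        # paired design: out-of-fold coverage identical because folds shared
        assert np.array_equal(np.isnan(results[0].probabilities),
                              np.isnan(results[1].probabilities))

    def test_identical_inputs_identical_metrics(self, tiny_setup):
        """Harness purity: rerunning a combination reproduces its metrics."""
        cohort, spec, cfg = tiny_setup
        r1 = run_ablation(cohort, ["N"], spec, cfg)[0]
        r2 = run_ablation(cohort, ["N"], spec, cfg)[0]
        assert r1.accuracy_mean == r2.accuracy_mean
        assert np.array_equal(r1.probabilities, r2.probabilities)

    def test_unknown_combination_rejected(self, tiny_setup):
        cohort, spec, cfg = tiny_setup
        with pytest.raises(ValueError):
            run_ablation(cohort, ["XYZ"], spec, cfg)


class TestRedundancy:
    def test_null_predictions_mostly_nonsignificant(self, rng):
        """Predictions independent of both biomarkers: ~alpha rejections."""
        from adprog.synthetic import CohortConfig, generate_cohort

        cohort = generate_cohort(CohortConfig(n_subjects=100, volume_shape=(8, 8, 8), seed=0))
        hits = 0
        n_sims = 100
        for _ in range(n_sims):
            preds = rng.integers(0, 2, 100)
            while len(np.unique(preds)) < 2:
                preds = rng.integers(0, 2, 100)
            res = redundancy_analysis(cohort, preds, preds)
            # biomarkers are class-conditional but predictions are random
            hits += res["ptau_given_AN"][1] <= 0.05
        assert hits / n_sims <= 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / n_sims) + 0.02

    def test_informed_predictions_detect_correlated_biomarker(self):
        """T-driven predictions expose Aβ differences when A correlates
        with T through the class (strong class-conditional Aβ shift)."""
        from adprog.synthetic import BiomarkerParams, CohortConfig, generate_cohort

        biomarkers = {
            "MD": BiomarkerParams(780.0, 110.0, 28.0, 8.0, 1.25, 0.10, 1.30, 0.12, 1.5e6, 1.5e5),
            "FD": BiomarkerParams(540.0, 110.0, 40.0, 8.0, 1.10, 0.10, 1.40, 0.12, 1.5e6, 1.5e5),
        }
        hits = 0
        for seed in range(10):
            cohort = generate_cohort(
                CohortConfig(n_subjects=300, volume_shape=(8, 8, 8),
                             biomarker_params=biomarkers, seed=seed)
            )
            # proxy for a T(N) model: threshold standardized p-tau
            ptau = cohort.biomarkers["ptau"].to_numpy()
            preds = (ptau > np.median(ptau)).astype(int)
            res = redundancy_analysis(cohort, preds, preds)
            hits += res["abeta_given_TN"][1] <= 0.05
        assert hits >= 8  # power > 0.8 at this configured effect

    def test_empty_predicted_group_degenerate(self):
        from adprog.synthetic import CohortConfig, generate_cohort

        cohort = generate_cohort(CohortConfig(n_subjects=20, volume_shape=(8, 8, 8), seed=1))
        with pytest.raises(DegenerateDataError):
            redundancy_analysis(cohort, np.zeros(20, int), np.zeros(20, int))
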