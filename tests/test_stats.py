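"""Statistics: ANOVA oracle, group tests, chi-square, permutation test."""

import numpy as np
import pandas as pd
import pytest

from _oracles import rm_anova_textbook
from adprog.stats import (
    DegenerateDataError,
    chi_square,
    group_difference,
    permutation_cluster_test,
    rm_anova,
    tau_positive,
)


class TestRmAnova:
    def test_constant_scores_give_zero_f(self):
        Y = np.full((8, 4), 5.0)
        res = rm_anova(Y, ["A"] * 4 + ["B"] * 4)
        assert res.F_time == 0.0 and res.F_interaction == 0.0

    def test_matches_textbook_decomposition(self, rng):
        Y = rng.normal(size=(4, 3)) + np.array([0, 1, 2])
        groups = np.array(["A", "A", "B", "B"])
        res = rm_anova(Y, groups)
        F_t, F_i = rm_anova_textbook(Y, groups)
        assert res.F_time == pytest.approx(F_t, abs=1e-10)
        assert res.F_interaction == pytest.approx(F_i, abs=1e-10)
        assert res.df_time == (2, 4)
        assert res.df_interaction == (2, 4)

    def test_matches_pingouin_mixed_anova(self, rng):
        import pingouin as pg

        n, t = 12, 4
        Y = rng.normal(size=(n, t)) + np.arange(t) * 0.7
        groups = np.array(["A"] * 5 + ["B"] * 7)
        res = rm_anova(Y, groups)
        df = pd.DataFrame(
            {
                "score": Y.ravel(),
                "subject": np.repeat(np.arange(n), t),
                "time": np.tile(np.arange(t), n),
                "group": np.repeat(groups, t),
            }
        )
        ref = pg.mixed_anova(df, dv="score", within="time", subject="subject", between="group")
        assert res.F_time == pytest.approx(float(ref.loc[1, "F"]), rel=1e-9)
        assert res.F_interaction == pytest.approx(float(ref.loc[2, "F"]), rel=1e-9)

    def test_invariance_to_constant_shift_and_relabeling(self, rng):
        Y = rng.normal(size=(10, 3))
        groups = np.array(["A"] * 5 + ["B"] * 5)
        res = rm_anova(Y, groups)
        shifted = rm_anova(Y + 100.0, groups)
        relabeled = rm_anova(Y, np.where(groups == "A", "B", "A"))
        assert res.F_time == pytest.approx(shifted.F_time, rel=1e-9)
        assert res.F_time == pytest.approx(relabeled.F_time, rel=1e-9)
        assert res.F_interaction == pytest.approx(relabeled.F_interaction, rel=1e-9)

    def test_interaction_type_one_error_near_nominal(self, rng):
        """Pure time effect, no group difference: interaction rejects at ~alpha."""
        hits = 0
        n_sims = 200
        for _ in range(n_sims):
            Y = rng.normal(size=(16, 3)) + np.array([0.0, 1.0, 2.0])
            res = rm_anova(Y, ["A"] * 8 + ["B"] * 8)
            hits += res.p_interaction <= 0.05
        rate = hits / n_sims
        assert 0.05 - 1.96 * np.sqrt(0.05 * 0.95 / n_sims) <= rate <= 0.05 + 1.96 * np.sqrt(
            0.05 * 0.95 / n_sims
        )

    def test_missing_panel_rejected(self):
        Y = np.ones((4, 3))
        Y[0, 1] = np.nan
        with pytest.raises(ValueError):
            rm_anova(Y, ["A", "A", "B", "B"])


class TestGroupDifference:
    def test_identical_groups_ranksum_p_one(self):
        stat, p = group_difference([1, 2, 3, 1, 2, 3], [0, 0, 0, 1, 1, 1], "ranksum")
        assert stat == 0.0 and p == 1.0

    def test_shifted_normals_tiny_p(self, rng):
        x = np.r_[rng.normal(0, 1, 50), rng.normal(3, 1, 50)]
        labels = np.r_[np.zeros(50), np.ones(50)]
        _, p_t = group_difference(x, labels, "t")
        _, p_r = group_difference(x, labels, "ranksum")
        assert p_t < 1e-6 and p_r < 1e-6

    def test_welch_t_matches_hand_formula(self):
        x = np.array([3.1, 2.8, 3.5, 3.0, 2.9, 3.2])
        y = np.array([2.1, 2.4, 2.0, 2.6, 2.2, 2.3])
        stat, _ = group_difference(np.r_[x, y], [0] * 6 + [1] * 6, "t")
        hand = (x.mean() - y.mean()) / np.sqrt(x.var(ddof=1) / 6 + y.var(ddof=1) / 6)
        assert stat == pytest.approx(hand, rel=1e-12)

    def test_zero_variance_both_groups_degenerate(self):
        with pytest.raises(DegenerateDataError):
            group_difference([1, 1, 2, 2], [0, 0, 1, 1], "t")


class TestTauPositive:
    def test_threshold_is_strict(self):
        pos, missing = tau_positive(np.array([10.0, 22.0, 21.8, 30.0]))
        assert pos.tolist() == [False, True, False, True]
        assert not missing.any()

    def test_scalar_above_cutoff(self):
        assert tau_positive(25.0) is True
        assert tau_positive(21.8) is False

    def test_missing_flagged(self):
        pos, missing = tau_positive(np.array([25.0, np.nan]))
        assert missing.tolist() == [False, True]


class TestChiSquare:
    def test_uniform_table_chi2_zero(self):
        res = chi_square([[10, 10], [10, 10]])
        assert res.chi2 == 0.0 and res.p == 1.0 and res.df == 1

    def test_three_by_two_hand_computation(self):
        """Pearson chi-square with expected counts from the margins."""
        table = np.array([[19, 7], [26, 21], [13, 11]], dtype=float)
        res = chi_square(table)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        hand = ((table - expected) ** 2 / expected).sum()
        assert res.chi2 == pytest.approx(hand, rel=1e-12)
        assert res.chi2 == pytest.approx(2.6158, abs=1e-4)
        assert res.df == 2

    def test_two_by_two_closed_form_sweep(self, rng):
        for _ in range(50):
            t = rng.integers(1, 30, size=(2, 2)).astype(float)
            a, b, c, d = t.ravel()
            n = t.sum()
            closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            assert chi_square(t).chi2 == pytest.approx(closed, rel=1e-10)

    def test_row_column_permutation_invariance(self, rng):
        t = rng.integers(1, 20, size=(3, 2)).astype(float)
        base = chi_square(t).chi2
        assert chi_square(t[[2, 0, 1]]).chi2 == pytest.approx(base)
        assert chi_square(t[:, [1, 0]]).chi2 == pytest.approx(base)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square([[0, 0], [5, 3]])


class TestPermutationClusterTest:
    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(16, 4))
        p1, s1, _ = permutation_cluster_test(X, None, n_perm=120, seed=9)
        p2, s2, _ = permutation_cluster_test(X, None, n_perm=120, seed=9)
        assert p1 == p2 and s1 == s2

    def test_saturates_at_minimum_for_separated_classes(self):
        X = np.vstack(
            [np.tile([28.0, 27, 26, 24], (8, 1)), np.tile([27.0, 22, 17, 10], (8, 1))]
        )
        labels = np.array([0] * 8 + [1] * 8)
        p, _, _ = permutation_cluster_test(X, labels, n_perm=150, seed=0)
        assert p == pytest.approx(1 / 151)

    def test_conservative_with_random_labels(self, rng):
        """Random labels on iid trajectories: rejection rate within the
        binomial CI of alpha (the re-clustered null makes this variant
        conservative, so low rates are acceptable)."""
        hits = 0
        for rep in range(20):
            X = rng.normal(size=(20, 4))
            labels = np.r_[np.zeros(10), np.ones(10)].astype(int)
            p, _, _ = permutation_cluster_test(X, labels, n_perm=100, seed=rep)
            hits += p <= 0.05
        assert hits / 20 <= 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / 20)

    def test_tiny_cluster_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        labels = np.r_[np.zeros(9), np.ones(1)].astype(int)
        with pytest.raises(DegenerateDataError):
            permutation_cluster_test(X, labels, n_perm=100, seed=0)

    def test_too_few_permutations_rejected(self, rng):
        with pytest.raises(ValueError):
            permutation_cluster_test(rng.normal(size=(10, 4)), None, n_perm=50, seed=0)
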