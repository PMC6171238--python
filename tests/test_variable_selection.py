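"""Mutual-information machinery, the eight greedy criteria, ensemble
ranking, DeLong test, and minimal-set selection."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from neurocascade import variable_selection as vs


def brute_force_mi(x, y):
    """Double-sum plug-in oracle over the joint count table."""
    x, y = np.asarray(x), np.asarray(y)
    n = len(x)
    mi = 0.0
    for xv in np.unique(x):
        for yv in np.unique(y):
            pxy = np.mean((x == xv) & (y == yv))
            if pxy == 0:
                continue
            px = np.mean(x == xv)
            py = np.mean(y == yv)
            mi += pxy * np.log(pxy / (px * py))
    return mi


class TestMutualInformation:
    def test_independent_fair_coins_zero(self):
        # exact product counts: every (x, y) cell appears equally often
        x = np.array([0, 0, 1, 1])
        y = np.array([0, 1, 0, 1])
        assert vs.mutual_information(x, y) == pytest.approx(0.0, abs=1e-14)

    def test_identical_balanced_binary_gives_log2(self):
        x = np.array([0, 1] * 10)
        assert vs.mutual_information(x, x) == pytest.approx(np.log(2), abs=1e-12)

    def test_matches_double_sum_oracle_on_3x3_table(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 3, 90)
        y = rng.integers(0, 3, 90)
        assert vs.mutual_information(x, y) == pytest.approx(
            brute_force_mi(x, y), abs=1e-12
        )

    def test_nonnegative_and_bounded_by_marginal_entropies(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.integers(0, 4, 60)
            y = rng.integers(0, 3, 60)
            mi = vs.mutual_information(x, y)
            assert mi >= 0
            assert mi <= min(vs.entropy(x), vs.entropy(y)) + 1e-12

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            vs.mutual_information(np.array([]), np.array([]))

    def test_conditional_mi_chain_consistency(self):
        # I(X;Y|Z) >= 0 and I(X;Y,Z) = I(X;Z) + I(X;Y|Z) (chain rule)
        rng = np.random.default_rng(2)
        x = rng.integers(0, 3, 200)
        z = rng.integers(0, 2, 200)
        y = (x + z + rng.integers(0, 2, 200)) % 3
        joint_yz = y * 2 + z
        lhs = vs.mutual_information(x, joint_yz)
        rhs = vs.mutual_information(x, z) + vs.conditional_mutual_information(x, y, z)
        assert lhs == pytest.approx(rhs, abs=1e-10)


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(3)
    n = 300
    y = np.array([0, 1] * (n // 2))
    relevant = y.copy()
    noise = rng.integers(0, 2, size=(n, 5))
    X = np.column_stack([noise[:, :2], relevant, noise[:, 2:]])
    return X, y


class TestCriteria:
    @pytest.mark.parametrize("criterion", vs.CRITERIA)
    def test_single_relevant_variable_ranks_first(self, planted, criterion):
        X, y = planted
        ranks = vs.rank_by_criterion(X, y, criterion)
        assert ranks[2] == 1  # the planted column

    @pytest.mark.parametrize("criterion", vs.CRITERIA)
    def test_output_is_a_permutation(self, criterion):
        rng = np.random.default_rng(4)
        X = rng.integers(0, 4, size=(80, 6))
        y = rng.integers(0, 2, 80)
        ranks = vs.rank_by_criterion(X, y, criterion)
        assert sorted(ranks) == list(range(1, 7))

    def test_mim_is_descending_univariate_mi(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 400)
        X = np.column_stack(
            [
                np.where(rng.random(400) < p, y, rng.integers(0, 2, 400))
                for p in (0.2, 0.9, 0.5, 0.0)
            ]
        )
        ranks = vs.rank_by_criterion(X, y, "mim")
        mis = [vs.mutual_information(X[:, j], y) for j in range(4)]
        expected_order = np.argsort([-m for m in mis], kind="stable")
        expected_ranks = np.empty(4, dtype=int)
        expected_ranks[expected_order] = np.arange(1, 5)
        assert np.array_equal(ranks, expected_ranks)

    def test_mrmr_penalises_duplicate_but_mim_does_not(self):
        """A duplicated informative variable should fall below a weaker but
        independent variable under MRMR; MIM keeps it second.  Scores are
        cross-checked by direct evaluation of the criterion formulas."""
        n = 60
        y = np.array([0, 1] * (n // 2))
        strong = y.copy()
        strong[::10] = 1 - strong[::10]  # 10% flips
        dup = strong.copy()
        weak = y.copy()
        weak[::3] = 1 - weak[::3]  # 33% flips, at different positions
        noise = np.array([0, 1, 1, 0] * (n // 4))
        X = np.column_stack([strong, dup, weak, noise])

        mim = vs.rank_by_criterion(X, y, "mim")
        mrmr = vs.rank_by_criterion(X, y, "mrmr")
        assert mim[0] == 1 and mim[1] == 2  # duplicate right behind the original
        assert mrmr[0] == 1
        assert mrmr[2] < mrmr[1]  # weak independent var outranks the duplicate

        # hand-computed second-step MRMR scores
        score_dup = vs.mutual_information(dup, y) - vs.mutual_information(dup, strong)
        score_weak = vs.mutual_information(weak, y) - vs.mutual_information(weak, strong)
        assert score_weak > score_dup

    def test_unknown_criterion_rejected(self):
        with pytest.raises(ValueError):
            vs.rank_by_criterion(np.zeros((4, 2), dtype=int), np.array([0, 1, 0, 1]), "foo")


class TestEnsemble:
    def test_identical_criteria_preserve_order(self):
        ranks = {c: np.array([2, 1, 3]) for c in vs.CRITERIA}
        table = vs.ensemble_rank(ranks, ["a", "b", "c"])
        assert table.ordered_names() == ["b", "a", "c"]

    def test_all_ones_mean_rank_is_first(self):
        ranks = {c: np.array([3, 1, 2]) for c in vs.CRITERIA[:4]}
        ranks.update({c: np.array([2, 1, 3]) for c in vs.CRITERIA[4:]})
        table = vs.ensemble_rank(ranks, ["a", "b", "c"])
        assert table.mean_rank[1] == 1.0
        assert table.ordered_names()[0] == "b"

    def test_tie_breaks_by_best_single_rank_then_name(self):
        # four criteria with order abc, four with the exact reversal: every
        # mean rank ties at 2.0
        fwd, rev = np.array([1, 2, 3]), np.array([3, 2, 1])
        ranks = {c: (fwd if i % 2 == 0 else rev) for i, c in enumerate(vs.CRITERIA)}
        table = vs.ensemble_rank(ranks, ["a", "b", "c"])
        assert np.allclose(table.mean_rank, 2.0)
        # a and c both reach best rank 1 -> alphabetical; b (best 2) is last
        assert table.ordered_names() == ["a", "c", "b"]

    def test_inconsistent_variable_sets_rejected(self):
        with pytest.raises(ValueError):
            vs.ensemble_rank({"mim": np.array([1, 2]), "jmi": np.array([1, 2, 3])})
        with pytest.raises(ValueError):
            vs.ensemble_rank({"mim": np.array([1, 1, 3])})

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(150, 8))
        y = (X[:, 3] + X[:, 1] + rng.normal(size=150) > 0).astype(int)
        perm = rng.permutation(8)
        base = vs.rank_ensemble(X, y)
        permuted = vs.rank_ensemble(X[:, perm], y)
        assert np.array_equal(base.mean_rank[perm], permuted.mean_rank)


class TestDeLong:
    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(7)
        s = rng.random(40)
        y = rng.integers(0, 2, 40)
        auc_a, auc_b, p = vs.delong_test(s, s.copy(), y)
        assert auc_a == auc_b
        assert p == 1.0

    def test_auc_equals_mann_whitney_oracle(self):
        rng = np.random.default_rng(8)
        s_a = rng.integers(0, 6, 60).astype(float)  # ties present
        s_b = rng.random(60)
        y = rng.integers(0, 2, 60)
        from tests.test_metrics import brute_force_auc

        auc_a, auc_b, _ = vs.delong_test(s_a, s_b, y)
        assert auc_a == pytest.approx(brute_force_auc(s_a, y), abs=1e-12)
        assert auc_b == pytest.approx(brute_force_auc(s_b, y), abs=1e-12)

    def test_auc_equals_trapezoidal_on_tie_free_data(self):
        rng = np.random.default_rng(9)
        s = rng.random(100)
        y = rng.integers(0, 2, 100)
        auc, _, _ = vs.delong_test(s, rng.random(100), y)
        assert auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_p_value_matches_paired_permutation_oracle(self):
        """Paired permutation oracle: swap the two scores within random
        subjects and recompute the AUC difference, 1e5 replicates."""
        rng = np.random.default_rng(10)
        n = 20
        y = np.array([1] * 8 + [0] * 12)
        s_a = y * 0.5 + rng.random(n)
        s_b = y * 0.2 + rng.random(n)
        _, _, p = vs.delong_test(s_a, s_b, y)

        def vect_auc(S):  # (R, n) score matrix -> (R,) AUCs
            pos = S[:, y == 1][:, :, None]
            neg = S[:, y == 0][:, None, :]
            return ((pos > neg) + 0.5 * (pos == neg)).mean(axis=(1, 2))

        observed = abs(vect_auc(s_a[None])[0] - vect_auc(s_b[None])[0])
        R = 100_000
        swap = rng.random((R, n)) < 0.5
        A = np.where(swap, s_b, s_a)
        B = np.where(swap, s_a, s_b)
        null = np.abs(vect_auc(A) - vect_auc(B))
        p_perm = (1 + np.sum(null >= observed - 1e-12)) / (R + 1)
        assert p == pytest.approx(p_perm, abs=0.05)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            vs.delong_test(np.ones(3), np.ones(3), np.ones(3))
        with pytest.raises(ValueError):
            vs.delong_test(np.ones(3), np.ones(4), np.array([0, 1, 0, 1]))


@pytest.fixture(scope="module")
def planted_sets():
    rng = np.random.default_rng(11)
    n, m, k_inf = 600, 30, 5
    y = rng.integers(0, 2, n)
    X = rng.normal(size=(n, m))
    X[:, :k_inf] += 0.9 * y[:, None]
    names = [f"v{j:02d}" for j in range(m)]
    ranking = vs.rank_ensemble(X, y, names)
    sets = vs.nested_set_evaluation(ranking, X, y, cv=5, seed=0)
    return ranking, sets, y


class TestNestedSets:
    def test_sets_are_nested(self, planted_sets):
        _, sets, _ = planted_sets
        for a, b in zip(sets, sets[1:]):
            assert set(a.members) < set(b.members)
            assert len(a.members) == a.i

    def test_auc_curve_saturates(self, planted_sets):
        """AUC rises with the first informative variables then plateaus."""
        _, sets, _ = planted_sets
        aucs = [s.auc_mean for s in sets]
        assert aucs[4] > aucs[0]  # growth phase
        assert abs(aucs[-1] - aucs[9]) < 0.03  # plateau after ~2x the planted size

    def test_minimal_set_recovers_planted_size(self, planted_sets):
        _, sets, _ = planted_sets
        chosen = vs.select_minimal_set(sets, alpha=0.05)
        assert chosen.i <= 10
        assert chosen.delong_p >= 0.05

    def test_single_variable_case(self):
        rng = np.random.default_rng(12)
        y = rng.integers(0, 2, 100)
        X = (y + rng.normal(size=100) * 0.5)[:, None]
        ranking = vs.rank_ensemble(X, y, ["only"])
        sets = vs.nested_set_evaluation(ranking, X, y, cv=3, seed=0)
        assert len(sets) == 1 and sets[0].delong_p == 1.0
        assert vs.select_minimal_set(sets).i == 1

    def test_smax_always_qualifies(self, planted_sets):
        _, sets, _ = planted_sets
        best = max(sets, key=lambda s: s.auc_mean)
        assert best.delong_p == 1.0
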