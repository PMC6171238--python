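"""Imputer correctness against brute-force oracles, observed-cell
preservation, and the dual evaluation protocol."""

import numpy as np
import pytest

from neurocascade import imputation as imp
from neurocascade.dataset import CohortDataset
from tests.conftest import toy_dataset


def make_random_dataset(n, m, n_masked, seed, labels=None):
    rng = np.random.default_rng(seed)
    values = rng.normal(size=(n, m)) * 3 + 10
    if labels is None:
        labels = rng.integers(0, 2, n)
    ds = toy_dataset(values, labels)
    flat = rng.choice(n * m, size=n_masked, replace=False)
    vals = ds.values.copy()
    # never mask the mmse column (index 0) so the dataset stays valid
    rows, cols = np.unravel_index(flat, (n, m))
    cols = np.where(cols == 0, 1, cols)
    vals[rows, cols] = np.nan
    return toy_dataset(vals, labels), ds


class TestMinMax:
    def test_positive_correlation_fills_max(self):
        # variable rises with the label -> blanks get the observed maximum
        values = np.array(
            [[1, 5.0], [1, 10.0], [1, 20.0], [1, 30.0], [1, np.nan], [1, 2.0]]
        )
        labels = np.array([0, 0, 1, 1, 1, 0])
        out = imp.minmax_impute(toy_dataset(values, labels))
        assert out.values[4, 1] == 30.0

    def test_negative_correlation_fills_min(self):
        values = np.array(
            [[1, 30.0], [1, 25.0], [1, 5.0], [1, 0.0], [1, np.nan], [1, 28.0]]
        )
        labels = np.array([0, 0, 1, 1, 1, 0])
        out = imp.minmax_impute(toy_dataset(values, labels))
        assert out.values[4, 1] == 0.0

    def test_constant_variable_fills_constant(self):
        values = np.array([[1, 7.0], [1, 7.0], [1, np.nan], [1, 7.0]])
        out = imp.minmax_impute(toy_dataset(values, np.array([0, 1, 1, 0])))
        assert out.values[2, 1] == 7.0

    def test_fill_within_observed_range(self, missing_cohort):
        out = imp.minmax_impute(missing_cohort)
        mask = missing_cohort.missing_mask
        for j in np.where(mask.any(axis=0))[0]:
            obs = missing_cohort.values[~mask[:, j], j]
            fills = out.values[mask[:, j], j]
            assert fills.min() >= obs.min() and fills.max() <= obs.max()


class TestKnn:
    def test_exact_duplicate_neighbors(self):
        values = np.array([[5, 1.0, 2.0], [5, 1.0, 2.0], [5, np.nan, 2.0]])
        values[2, 1] = np.nan
        ds = toy_dataset(values, np.array([0, 1, 0]))
        out = imp.knn_impute(ds, k=2)
        assert out.values[2, 1] == pytest.approx(1.0)

    def test_k1_equals_nearest_neighbor(self):
        rng = np.random.default_rng(0)
        ds, complete = make_random_dataset(15, 5, 2, seed=1)
        out = imp.knn_impute(ds, k=1)
        z = imp._zscore_observed(ds.values, ds.missing_mask)
        for i, j in zip(*np.where(ds.missing_mask)):
            d = imp.pairwise_partial_distances(z, i)
            d[i] = np.nan
            eligible = np.where(~ds.missing_mask[:, j] & np.isfinite(d))[0]
            nearest = eligible[np.argmin(d[eligible])]
            assert out.values[i, j] == pytest.approx(ds.values[nearest, j])

    def test_matches_exhaustive_distance_oracle(self):
        """Brute-force oracle: loop over all pairs, compute the co-observed
        scaled Euclidean distance explicitly, sort, average the k donors."""
        ds, _ = make_random_dataset(20, 6, 3, seed=2)
        out = imp.knn_impute(ds, k=5)
        X = ds.values
        mask = ds.missing_mask
        n, m = X.shape
        mu = np.array([X[~mask[:, j], j].mean() for j in range(m)])
        sd = np.array([X[~mask[:, j], j].std() or 1.0 for j in range(m)])
        Z = (X - mu) / sd
        for i, j in zip(*np.where(mask)):
            dists = []
            for other in range(n):
                if other == i or mask[other, j]:
                    continue
                co = [~mask[i, t] and ~mask[other, t] for t in range(m)]
                n_co = sum(co)
                if n_co == 0:
                    continue
                ssq = sum(
                    (Z[i, t] - Z[other, t]) ** 2 for t in range(m) if co[t]
                )
                dists.append((np.sqrt(ssq * m / n_co), other))
            dists.sort()
            donors = [o for _, o in dists[:5]]
            assert out.values[i, j] == pytest.approx(
                np.mean([X[o, j] for o in donors]), abs=1e-10
            )

    def test_row_permutation_equivariance(self):
        ds, _ = make_random_dataset(25, 5, 4, seed=3)
        out = imp.knn_impute(ds, k=3)
        perm = np.random.default_rng(4).permutation(25)
        ds_p = ds.take_rows(perm)
        out_p = imp.knn_impute(ds_p, k=3)
        assert np.allclose(out_p.values, out.values[perm])


class TestLls:
    def test_exact_linear_function_recovered(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        target = 2.0 * a - 3.0 * b + 1.0
        values = np.column_stack([np.full(30, 1.0), target, a, b])
        values[0, 1] = np.nan
        values[7, 1] = np.nan
        ds = toy_dataset(values, rng.integers(0, 2, 30))
        out = imp.lls_impute(ds, k_vars=2)
        truth = 2.0 * a - 3.0 * b + 1.0
        assert out.values[0, 1] == pytest.approx(truth[0], abs=1e-8)
        assert out.values[7, 1] == pytest.approx(truth[7], abs=1e-8)

    def test_identical_predictor_reproduced(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=20)
        values = np.column_stack([np.ones(20), x.copy(), x.copy()])
        values[3, 1] = np.nan
        ds = toy_dataset(values, rng.integers(0, 2, 20))
        out = imp.lls_impute(ds, k_vars=1)
        assert out.values[3, 1] == pytest.approx(x[3], abs=1e-8)

    def test_matches_normal_equations_oracle(self):
        """Independent oracle: build the normal equations X'X b = X'y
        explicitly with the same top-correlated predictors and solve by
        pseudo-inverse."""
        rng = np.random.default_rng(7)
        base = rng.normal(size=(30, 2))
        noise = rng.normal(size=(30, 5)) * 0.3
        values = np.column_stack(
            [
                np.ones(30),
                base @ [1.0, 0.5] + noise[:, 0],
                base[:, 0] + noise[:, 1],
                base[:, 1] + noise[:, 2],
                base @ [0.3, -0.7] + noise[:, 3],
            ]
        )
        values[2, 1] = np.nan
        values[11, 1] = np.nan
        ds = toy_dataset(values, rng.integers(0, 2, 30))
        k_vars = 3
        out = imp.lls_impute(ds, k_vars=k_vars)

        X = ds.values
        mask = ds.missing_mask
        j = 1
        import pandas as pd

        corr = pd.DataFrame(X).corr(min_periods=3).to_numpy()
        np.fill_diagonal(corr, np.nan)
        cj = np.abs(corr[:, j])
        cand = np.where(np.isfinite(cj))[0]
        top = cand[np.argsort(-cj[cand], kind="stable")[:k_vars]]
        rows = ~mask[:, j] & ~mask[:, top].any(axis=1)
        D = np.column_stack([np.ones(rows.sum()), X[rows][:, top]])
        beta = np.linalg.pinv(D.T @ D) @ D.T @ X[rows, j]
        for i in (2, 11):
            expected = float(np.concatenate([[1.0], X[i, top]]) @ beta)
            assert out.values[i, j] == pytest.approx(expected, abs=1e-8)


class TestMi:
    def test_seed_determinism(self):
        ds, _ = make_random_dataset(60, 5, 6, seed=8)
        a = imp.mi_impute(ds, m=3, seed=42)
        b = imp.mi_impute(ds, m=3, seed=42)
        assert np.array_equal(a.values, b.values)
        c = imp.mi_impute(ds, m=3, seed=43)
        assert not np.array_equal(a.values, c.values)

    def test_mcar_gaussian_bias_near_zero(self):
        """On MCAR multivariate-Gaussian data the chained-regression MI fill
        should be unbiased for the missing cells."""
        rng = np.random.default_rng(9)
        n = 1000
        shared = rng.normal(size=(n, 1))
        X = shared + rng.normal(size=(n, 4)) * 0.5
        truth = X.copy()
        miss_rows = rng.choice(n, 120, replace=False)
        X[miss_rows, 2] = np.nan
        ds = toy_dataset(X, rng.integers(0, 2, n))
        out = imp.mi_impute(ds, m=5, seed=0)
        bias = np.mean(out.values[miss_rows, 2] - truth[miss_rows, 2])
        assert abs(bias) < 0.1


class TestProtocol:
    def test_observed_cells_preserved_by_every_method(self, missing_cohort):
        obs = ~missing_cohort.missing_mask
        for method in imp.METHODS:
            kwargs = {"seed": 1} if method == "mi" else {}
            out = imp.impute(missing_cohort, method, **kwargs)
            assert np.array_equal(out.values[obs], missing_cohort.values[obs])
            assert np.array_equal(out.imputed_mask, missing_cohort.missing_mask)

    def test_fully_missing_variable_rejected(self):
        values = np.array([[1.0, np.nan], [2.0, np.nan]])
        ds = toy_dataset(values, np.array([0, 1]))
        with pytest.raises(ValueError):
            imp.minmax_impute(ds)

    def test_imputation_error_oracle(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=(10, 10))
        b = rng.normal(size=(10, 10))
        mask = rng.random((10, 10)) < 0.3
        expected = np.sqrt(sum(
            (a[i, j] - b[i, j]) ** 2
            for i in range(10)
            for j in range(10)
            if mask[i, j]
        ))
        assert imp.imputation_error(a, b, mask) == pytest.approx(expected, abs=1e-12)

    def test_imputation_error_trivial_cases(self):
        a = np.ones((3, 3))
        assert imp.imputation_error(a, a, np.ones((3, 3), bool)) == 0.0
        b = a.copy()
        b[1, 1] += 3.0
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        assert imp.imputation_error(a, b, mask) == pytest.approx(3.0)

    def test_mask_artificial_count_conservation(self, default_cohort):
        reference = np.zeros((10, default_cohort.n_variables), bool)
        reference[:3, 6] = True
        reference[:5, 8] = True
        masked = imp.mask_artificial(default_cohort, reference, seed=0)
        counts = masked.missing_mask.sum(axis=0)
        assert counts[6] == 3 and counts[8] == 5 and counts.sum() == 8

    def test_mask_artificial_empty_reference_is_noop(self, default_cohort):
        reference = np.zeros((5, default_cohort.n_variables), bool)
        masked = imp.mask_artificial(default_cohort, reference, seed=0)
        assert masked.is_complete

    def test_mask_artificial_seeds_move_placement_not_counts(self, default_cohort):
        reference = np.zeros((50, default_cohort.n_variables), bool)
        reference[:20, 7] = True
        a = imp.mask_artificial(default_cohort, reference, seed=1)
        b = imp.mask_artificial(default_cohort, reference, seed=2)
        assert a.missing_mask.sum(axis=0)[7] == b.missing_mask.sum(axis=0)[7] == 20
        assert not np.array_equal(a.missing_mask, b.missing_mask)

    def test_indirect_evaluation_identical_matrices_tie_broken_by_direct(self):
        ds, complete = make_random_dataset(120, 6, 10, seed=11)
        filled = imp.knn_impute(ds, k=3)
        sets = [
            imp.ImputedMatrix(filled.values.copy(), "knn", filled.imputed_mask),
            imp.ImputedMatrix(filled.values.copy(), "lls", filled.imputed_mask),
        ]
        classifiers = {"lr": imp.default_classifier_suite()["logistic_regression"]}
        report = imp.indirect_evaluation(
            ds, sets, classifiers, direct_errors={"knn": 1.0, "lls": 2.0}
        )
        assert report.indirect_auc["knn"] == report.indirect_auc["lls"]
        assert report.winner == "knn"
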