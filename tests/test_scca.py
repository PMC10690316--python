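import numpy as np
import pytest
import scipy.linalg

from multifuse.scca import (MultiCCA, SparseCCA, cca_permute,
                            l1_constrained_unit_vector, multi_cca,
                            multi_cca_permute, soft_threshold, sparse_cca)
from multifuse.simulate import MultiViewScenario, gen_multiview
from multifuse import standardize

from conftest import sign_aligned_cosine, standardized_pair


class TestSoftThreshold:
    @pytest.mark.parametrize("a,delta,expected", [
        ((2.5, -0.3, 0.0), 0.5, (2.0, 0.0, 0.0)),
        ((1.0, -2.0, 0.5), 0.0, (1.0, -2.0, 0.5)),
        ((1.0, -2.0, 0.5), 2.0, (0.0, 0.0, 0.0)),
    ])
    def test_closed_form(self, a, delta, expected):
        np.testing.assert_allclose(soft_threshold(np.array(a), delta), expected)

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.ones(2), -0.1)


class TestL1ConstrainedUnitVector:
    def test_single_active_coordinate(self):
        w = l1_constrained_unit_vector(np.array([3.0, 0.0, 0.0]), 1.0)
        np.testing.assert_allclose(w, [1, 0, 0])

    def test_non_binding_bound(self):
        w = l1_constrained_unit_vector(np.array([1.0, 1.0]), np.sqrt(2))
        np.testing.assert_allclose(w, [1 / np.sqrt(2)] * 2)

    def test_matches_grid_search_oracle(self):
        a = np.array([3.0, 1.0, 0.5])
        c = 1.2
        w = l1_constrained_unit_vector(a, c)
        # brute-force the threshold on a fine grid
        best, best_val = None, -np.inf
        for delta in np.arange(0.0, 3.0, 1e-6):
            s = soft_threshold(a, delta)
            norm = np.linalg.norm(s)
            if norm == 0:
                continue
            cand = s / norm
            if np.abs(cand).sum() <= c + 1e-9 and cand @ a > best_val:
                best, best_val = cand, cand @ a
        np.testing.assert_allclose(w, best, atol=1e-4)

    def test_feasibility(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.standard_normal(8)
            c = rng.uniform(1.0, np.sqrt(8))
            w = l1_constrained_unit_vector(a, c)
            assert np.linalg.norm(w) <= 1 + 1e-8
            assert np.abs(w).sum() <= c + 1e-6

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            l1_constrained_unit_vector(np.zeros(3), 1.0)


def classical_first_canonical_correlation(X, Z):
    """Generalized-eigenvalue CCA oracle (full whitening, first component)."""
    Wx = scipy.linalg.fractional_matrix_power(X.T @ X, -0.5).real
    Wz = scipy.linalg.fractional_matrix_power(Z.T @ Z, -0.5).real
    return np.linalg.svd(Wx @ (X.T @ Z) @ Wz, compute_uv=False)[0]


class TestSparseCCA:
    def test_self_correlation_is_one(self):
        X, _ = standardized_pair(20, 3, 3, 0)
        res = sparse_cca(X, X.copy(), 1.0, 1.0)
        assert res.correlations[0] == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("seed", range(20))
    def test_whitened_mode_matches_classical_cca(self, seed):
        X, Z = standardized_pair(30, 4, 3, seed)
        res = sparse_cca(X, Z, 1.0, 1.0, whiten=True, max_iter=500, tol=1e-10)
        oracle = classical_first_canonical_correlation(X, Z)
        assert abs(res.correlations[0]) == pytest.approx(oracle, abs=1e-6)

    def test_recovers_planted_sparse_loadings(self, default_multiview):
        ds, truth = default_multiview
        res = sparse_cca(ds.views[0], ds.views[1], 0.3, 0.3)
        assert sign_aligned_cosine(res.u[:, 0], truth["W"][0][:, 0]) >= 0.9
        assert sign_aligned_cosine(res.v[:, 0], truth["W"][1][:, 0]) >= 0.9

    def test_unit_norm_and_l1_feasibility(self):
        X, Z = standardized_pair(40, 12, 9, 5)
        res = sparse_cca(X, Z, 0.4, 0.5, K=3)
        for k in range(3):
            for w, frac, p in ((res.u[:, k], 0.4, 12), (res.v[:, k], 0.5, 9)):
                assert np.linalg.norm(w) <= 1 + 1e-8
                assert np.abs(w).sum() <= max(1, frac * np.sqrt(p)) + 1e-6

    @pytest.mark.parametrize("seed", range(5))
    def test_deflated_components_weakly_correlated(self, seed):
        # deflation gives only approximate decorrelation; on well-conditioned
        # instances (n >> p, non-binding bounds) the residual correlation is
        # small, and exact zero under full whitening
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((1000, 10))
        Z = rng.standard_normal((1000, 8))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        Z = (Z - Z.mean(0)) / Z.std(0, ddof=1)
        res = sparse_cca(X, Z, 1.0, 1.0, K=2)
        assert abs(np.corrcoef(X @ res.u[:, 0], X @ res.u[:, 1])[0, 1]) <= 0.15
        resw = sparse_cca(X, Z, 1.0, 1.0, K=2, whiten=True,
                          max_iter=500, tol=1e-10)
        assert abs(np.corrcoef(X @ resw.u[:, 0],
                               X @ resw.u[:, 1])[0, 1]) <= 1e-6

    def test_sparsity_monotone_in_bound(self):
        X, Z = standardized_pair(50, 20, 20, 3)
        counts = [sparse_cca(X, Z, f, f).nonzero_counts[0][0]
                  for f in (0.8, 0.6, 0.4, 0.2, 0.1)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_k_too_large_rejected(self):
        X, Z = standardized_pair(20, 4, 3, 1)
        with pytest.raises(ValueError, match="K"):
            sparse_cca(X, Z, 1.0, 1.0, K=4)


class TestCCAPermute:
    def test_fisher_transform_value(self):
        assert np.arctanh(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_planted_signal_is_significant(self, default_multiview):
        ds, _ = default_multiview
        tuning = cca_permute(ds.views[0], ds.views[1], grid=[0.2, 0.4],
                             n_permutations=99, seed=1)
        assert tuning.pvalue <= 0.02
        assert tuning.zstats[tuning.best_index] == tuning.zstats.max()

    def test_single_grid_point_is_best(self):
        X, Z = standardized_pair(40, 5, 5, 2)
        tuning = cca_permute(X, Z, grid=[0.5], n_permutations=20, seed=0)
        assert tuning.best == (0.5, 0.5)

    def test_pvalue_has_permutation_granularity(self):
        X, Z = standardized_pair(40, 5, 5, 4)
        tuning = cca_permute(X, Z, grid=[0.5], n_permutations=19, seed=0)
        assert tuning.pvalue >= 1 / 20
        assert tuning.pvalue <= 1.0

    def test_too_few_permutations_rejected(self):
        X, Z = standardized_pair(30, 4, 4, 0)
        with pytest.raises(ValueError):
            cca_permute(X, Z, grid=[0.5], n_permutations=5, seed=0)


class TestMultiCCA:
    def test_identical_views_fully_correlated(self):
        X, _ = standardized_pair(30, 4, 3, 0)
        res = multi_cca([X, X.copy(), X.copy()], penalties=[2, 2, 2])
        np.testing.assert_allclose(res.correlations[0], 1.0, atol=1e-6)

    @pytest.mark.parametrize("seed", range(0, 50, 7))
    def test_objective_non_decreasing(self, seed):
        rng = np.random.default_rng(seed)
        views = [rng.standard_normal((30, p)) for p in (4, 5, 3)]
        views = [(v - v.mean(0)) / v.std(0, ddof=1) for v in views]
        res = multi_cca(views, penalties=[1.5, 1.5, 1.5])
        assert np.diff(np.array(res.objective_trace)).min() >= -1e-8

    def test_recovers_shared_factor(self):
        ds, truth = gen_multiview(MultiViewScenario(p=(50, 50, 50), seed=0))
        ds_std, _ = standardize(ds)
        pen = max(1, 0.3 * np.sqrt(50))
        res = multi_cca(ds_std.matrices(), penalties=[pen] * 3)
        for i in range(3):
            assert sign_aligned_cosine(res.weights[i][:, 0],
                                       truth["W"][i][:, 0]) >= 0.85

    def test_two_views_rejected(self):
        X, Z = standardized_pair(20, 3, 3, 0)
        with pytest.raises(ValueError, match="3 views"):
            MultiCCA([X, Z])

    def test_penalty_bounds_validated(self):
        X, _ = standardized_pair(20, 4, 4, 0)
        with pytest.raises(ValueError, match="penalty"):
            multi_cca([X, X.copy(), X.copy()], penalties=[0.5, 2, 2])


class TestMultiCCAPermute:
    def test_single_grid_point_is_best(self):
        rng = np.random.default_rng(0)
        views = [rng.standard_normal((30, p)) for p in (4, 4, 3)]
        views = [(v - v.mean(0)) / v.std(0, ddof=1) for v in views]
        tuning = multi_cca_permute(views, grid=[[1.5, 1.5, 1.5]],
                                   n_permutations=20, seed=0)
        assert tuning.best == [1.5, 1.5, 1.5]

    def test_shared_factor_detected(self):
        ds, _ = gen_multiview(MultiViewScenario(n=120, p=(20, 20, 20), seed=2))
        ds_std, _ = standardize(ds)
        tuning = multi_cca_permute(ds_std.matrices(),
                                   grid=[[2.0] * 3, [3.0] * 3],
                                   n_permutations=99, seed=5)
        assert tuning.pvalue <= 0.02
        assert tuning.zstats[tuning.best_index] == tuning.zstats.max()
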