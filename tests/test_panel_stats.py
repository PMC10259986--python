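"""Correlation statistics and standardized PCA with parallel analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from htdkit.panel_stats import (
    LigandPanel,
    correlation_table,
    parallel_analysis,
    pca_standardized,
    pearson_with_p,
    spearman_with_p,
)


def panel_from(arr, cols):
    return LigandPanel(pd.DataFrame(arr, columns=cols))


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = pearson_with_p(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-12

    def test_orthogonal_after_centering(self):
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, -1.0])
        r, _ = pearson_with_p(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_known_five_point_example(self):
        r, p = pearson_with_p([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert r == pytest.approx(0.8, abs=1e-12)
        assert p == pytest.approx(0.104, abs=1e-3)

    def test_matches_scipy(self, rng):
        x, y = rng.normal(size=14), rng.normal(size=14)
        r, p = pearson_with_p(x, y)
        ref = stats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_p([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_p([1, 2], [3, 4])

    def test_missing_values_dropped_pairwise(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [1.1, 2.2, 3.0, 4.1, 5.3]
        r, _ = pearson_with_p(x, y)
        r_ref, _ = pearson_with_p([1, 2, 4, 5], [1.1, 2.2, 4.1, 5.3])
        assert r == pytest.approx(r_ref)


class TestSpearman:
    def test_monotone_nonlinear(self):
        x = np.linspace(0, 3, 8)
        rho, _ = spearman_with_p(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_reversed_order(self):
        rho, _ = spearman_with_p([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_rank_then_pearson_oracle(self):
        rho, _ = spearman_with_p([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        ranks_r, _ = pearson_with_p(
            stats.rankdata([1, 2, 3, 4, 5]), stats.rankdata([2, 1, 4, 3, 5])
        )
        assert rho == pytest.approx(0.8, abs=1e-12)
        assert rho == pytest.approx(ranks_r, abs=1e-12)

    def test_exact_permutation_p_small_n(self):
        """n < 10 uses full enumeration; cross-check by direct enumeration."""
        import itertools

        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        rho, p = spearman_with_p(x, y)
        count = 0
        total = 0
        for perm in itertools.permutations(range(5)):
            r = np.corrcoef(x, y[list(perm)])[0, 1]
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_t_approximation_large_n_matches_scipy(self, rng):
        x, y = rng.normal(size=14), rng.normal(size=14)
        rho, p = spearman_with_p(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


class TestPCA:
    def test_perfectly_correlated_pair_is_rank_one(self, rng):
        x = rng.normal(size=12)
        panel = panel_from(np.column_stack([x, 3 * x + 1]), ["a", "b"])
        res = pca_standardized(panel)
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-12)

    def test_variance_fractions_sum_to_one(self, rng):
        panel = panel_from(rng.normal(size=(10, 4)), list("abcd"))
        res = pca_standardized(panel)
        assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_eigenvalues_match_characteristic_polynomial_oracle(self, rng):
        """3x3 correlation-matrix eigenvalues vs the cubic's roots."""
        data = rng.normal(size=(9, 3))
        panel = panel_from(data, list("abc"))
        res = pca_standardized(panel)
        z = (data - data.mean(0)) / data.std(0, ddof=1)
        c = z.T @ z / (len(data) - 1)
        # characteristic polynomial det(C - t I) for 3x3, expanded
        coeffs = [
            -1.0,
            np.trace(c),
            -0.5 * (np.trace(c) ** 2 - np.trace(c @ c)),
            np.linalg.det(c),
        ]
        roots = np.sort(np.roots(coeffs).real)[::-1]
        np.testing.assert_allclose(res.eigenvalues, roots, atol=1e-10)

    def test_scores_covariance_is_diagonal_eigenvalues(self, rng):
        panel = panel_from(rng.normal(size=(12, 5)), list("abcde"))
        res = pca_standardized(panel)
        cov = np.cov(res.scores.to_numpy(), rowvar=False, ddof=1)
        np.testing.assert_allclose(cov, np.diag(res.eigenvalues), atol=1e-9)

    def test_loadings_orthonormal(self, rng):
        panel = panel_from(rng.normal(size=(12, 5)), list("abcde"))
        L = pca_standardized(panel).loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(5), atol=1e-9)

    def test_sign_convention_deterministic(self, rng):
        data = rng.normal(size=(10, 3))
        res1 = pca_standardized(panel_from(data, list("abc")))
        res2 = pca_standardized(panel_from(data, list("abc")))
        pd.testing.assert_frame_equal(res1.loadings, res2.loadings)
        for pc in res1.loadings.columns:
            col = res1.loadings[pc]
            assert col.iloc[np.argmax(np.abs(col.to_numpy()))] > 0

    def test_zero_variance_column_flagged(self, rng):
        data = np.column_stack([rng.normal(size=8), np.ones(8)])
        with pytest.raises(ValueError):
            pca_standardized(panel_from(data, ["a", "b"]))

    def test_listwise_missing_dropped(self, rng):
        data = rng.normal(size=(10, 3))
        df = pd.DataFrame(data, columns=list("abc"))
        df.iloc[0, 1] = np.nan
        res = pca_standardized(LigandPanel(df))
        assert len(res.scores) == 9


class TestParallelAnalysis:
    def test_pure_noise_retains_nothing(self, rng):
        data = rng.standard_normal((14, 6))
        panel = panel_from(data, list("abcdef"))
        res = pca_standardized(panel, retention=(300, 95.0, 7))
        # most eigenvalues of pure noise fall below the 95th-percentile bar
        assert len(res.retained) <= 1

    def test_two_planted_factors_retained(self, rng):
        """A panel dominated by two orthogonal factors retains exactly 2 PCs."""
        n, p = 14, 6
        f1, f2 = rng.standard_normal(n), rng.standard_normal(n)
        load1 = np.array([1, 1, 1, 0, 0, 0.0])
        load2 = np.array([0, 0, 0, 1, 1, 1.0])
        data = np.outer(f1, load1) + np.outer(f2, load2) + 0.05 * rng.standard_normal((n, p))
        res = pca_standardized(panel_from(data, list("abcdef")), retention=(300, 95.0, 7))
        assert res.retained == ["PC1", "PC2"]

    def test_thresholds_reproducible_under_seed(self):
        t1 = parallel_analysis((14, 6), n_sims=100, seed=3)
        t2 = parallel_analysis((14, 6), n_sims=100, seed=3)
        np.testing.assert_array_equal(t1, t2)
        assert np.all(np.diff(t1) < 0)  # thresholds fall with rank


class TestCorrelationTable:
    def test_all_pairs_reported(self, rng):
        panel = panel_from(rng.normal(size=(10, 3)), list("abc"))
        table = correlation_table(panel)
        assert len(table) == 3
        assert {"pearson_r", "spearman_rho", "pearson_p", "spearman_p"} <= set(table.columns)
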