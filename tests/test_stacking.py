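"""Stacked ridge regression oracle: grids, blocks, both levels, the test."""

import numpy as np
import pytest
from scipy import stats

from fedgwas import PipelineConfig, SimulationConfig, simulate_study
from fedgwas.config import GridConfig
from fedgwas.stacking import (
    build_ridge_grid,
    chi2_test,
    level0_fit_predict,
    level1_fit,
    make_blocks,
    run_plaintext_gwas,
)


class TestGrid:
    def test_heritability_grid_endpoints_and_midpoints(self):
        grid = build_ridge_grid(1000, 10, 5)
        assert grid.h == pytest.approx([0.01, 0.255, 0.50, 0.745, 0.99])

    def test_level0_penalty_value(self):
        grid = build_ridge_grid(1000, 10, 5)
        # h = 0.5 -> lambda = M (1 - 0.25) / 0.25 = 3 M
        assert grid.lambdas[2] == pytest.approx(3000.0)

    def test_level1_penalty_value(self):
        grid = build_ridge_grid(1000, 10, 5)
        # omega = (B R / M) lambda = (50/1000) * 3000
        assert grid.omegas[2] == pytest.approx(150.0)

    def test_lambdas_strictly_decreasing(self):
        grid = build_ridge_grid(500, 4, 7)
        assert np.all(np.diff(grid.lambdas) < 0)

    def test_single_penalty_rejected(self):
        with pytest.raises(ValueError):
            build_ridge_grid(100, 2, 1)


class TestBlocks:
    @pytest.mark.parametrize("m,size,expected", [
        (10, 4, [(0, 4), (4, 8), (8, 10)]),
        (5, 10, [(0, 5)]),
    ])
    def test_boundaries(self, m, size, expected):
        assert make_blocks(m, size) == expected

    def test_blocks_reassemble_full_range(self):
        blocks = make_blocks(1003, 97)
        covered = np.concatenate([np.arange(s, e) for s, e in blocks])
        assert np.array_equal(covered, np.arange(1003))


class TestLevel0:
    def test_infinite_shrinkage_zeroes_predictions(self, rng):
        X = rng.standard_normal((12, 2))
        y = rng.standard_normal(12)
        folds = np.arange(12) % 3
        grid = build_ridge_grid(2, 1, 2)
        grid.lambdas[:] = 1e12
        W = level0_fit_predict(X, y, folds, grid, [(0, 2)])
        assert np.abs(W).max() < 1e-9

    def test_matches_per_fold_normal_equations(self, rng):
        """Independent oracle: explicit normal-equations solve per fold."""
        X = rng.standard_normal((6, 2))
        y = rng.standard_normal(6)
        folds = np.array([0, 1, 0, 1, 0, 1])
        lam = 3.5
        grid = build_ridge_grid(2, 1, 2)
        grid.lambdas[:] = lam
        W = level0_fit_predict(X, y, folds, grid, [(0, 2)])
        for k in (0, 1):
            tr, te = folds != k, folds == k
            beta = np.linalg.solve(X[tr].T @ X[tr] + lam * np.eye(2), X[tr].T @ y[tr])
            assert np.abs(W[te, 0] - X[te] @ beta).max() < 1e-10

    def test_feature_matrix_shape(self, rng):
        X = rng.standard_normal((20, 6))
        y = rng.standard_normal(20)
        grid = build_ridge_grid(6, 3, 4)
        W = level0_fit_predict(X, y, np.arange(20) % 4, grid, make_blocks(6, 2))
        assert W.shape == (20, 3 * 4)

    def test_empty_fold_rejected(self, rng):
        X = rng.standard_normal((6, 2))
        with pytest.raises(ValueError, match="empty fold"):
            level0_fit_predict(
                X, np.zeros(6), np.zeros(6, dtype=int),
                build_ridge_grid(2, 1, 2), [(0, 2)], n_folds=2,
            )


class TestLevel1:
    def test_identity_feature_toy_solution(self):
        """W = I, omega = 1: eta = (I + I)^{-1} y = y / 2 on the training part."""
        W = np.eye(2)
        y = np.array([2.0, 4.0])
        grid = build_ridge_grid(2, 1, 2)
        grid.omegas[:] = 1.0
        eta = np.linalg.solve(W.T @ W + 1.0 * np.eye(2), W.T @ y)
        assert eta == pytest.approx([1.0, 2.0])

    def test_orthogonal_phenotype_gives_null_fit(self, rng):
        W = np.zeros((10, 3))
        W[:5, 0] = 1.0
        y = np.concatenate([np.zeros(5), rng.standard_normal(5)])
        y[5:] -= y[5:].mean()
        grid = build_ridge_grid(3, 1, 3)
        folds = np.arange(10) % 2
        fit = level1_fit(W, y - W @ np.linalg.lstsq(W, y, rcond=None)[0], folds, grid)
        assert np.abs(fit.y_hat).max() < 0.5

    def test_perfect_predictor_selects_weakest_penalty(self, rng):
        y = rng.standard_normal(40)
        W = np.column_stack([y, rng.standard_normal((40, 2)) * 0.01])
        grid = build_ridge_grid(1000, 1, 3)  # omegas span strong -> weak
        fit = level1_fit(W, y, np.arange(40) % 4, grid)
        assert fit.r_star == 2  # smallest omega wins when a perfect column exists
        assert fit.rss[2] < 0.05 * float(y @ y)

    def test_matches_closed_form_per_fold(self, rng):
        W = rng.standard_normal((12, 4))
        y = rng.standard_normal(12)
        folds = np.arange(12) % 3
        grid = build_ridge_grid(100, 2, 2)
        fit = level1_fit(W, y, folds, grid)
        for k in range(3):
            tr = folds != k
            for r in range(2):
                eta = np.linalg.solve(
                    W[tr].T @ W[tr] + grid.omegas[r] * np.eye(4), W[tr].T @ y[tr]
                )
                assert np.abs(fit.eta[k][:, r] - eta).max() < 1e-10


class TestChi2:
    def test_orthogonal_snp_gives_null(self):
        x = np.array([[1.0], [1.0], [-1.0], [-1.0]])
        res_vec = np.array([1.0, -1.0, 1.0, -1.0])
        chisq, p, _ = chi2_test(x, res_vec, np.zeros(4), 1)
        assert chisq[0] == pytest.approx(0.0, abs=1e-12)
        assert p[0] == pytest.approx(1.0)

    def test_worked_arithmetic_example(self):
        x = np.array([[1.0], [-1.0], [1.0], [-1.0]])
        y_proj = np.array([1.0, -1.0, 0.0, 0.0])
        chisq, _, sigma2 = chi2_test(x, y_proj, np.zeros(4), 1)
        assert sigma2 == pytest.approx(2 / 3)
        assert chisq[0] == pytest.approx(1.5)

    def test_hwe_threshold_p_value_correspondence(self):
        # chi2 = 23.928 <-> p = 1.0e-6 at 2 significant figures
        p = stats.chi2.sf(23.928, df=1)
        assert p == pytest.approx(1.0e-6, rel=5e-3)

    def test_null_vector_rejected(self):
        with pytest.raises(ValueError, match="null test vector"):
            chi2_test(np.zeros((4, 1)), np.ones(4), np.zeros(4), 1)

    def test_invariance_under_permutation_and_sign_flip(self, rng):
        x = rng.standard_normal((30, 3))
        y_proj = rng.standard_normal(30)
        y_hat = rng.standard_normal(30) * 0.3
        chisq, _, _ = chi2_test(x, y_proj, y_hat, 2)
        perm = rng.permutation(30)
        chisq_p, _, _ = chi2_test(x[perm], y_proj[perm], y_hat[perm], 2)
        chisq_s, _, _ = chi2_test(-x, y_proj, y_hat, 2)
        assert np.abs(chisq - chisq_p).max() < 1e-10
        assert np.abs(chisq - chisq_s).max() < 1e-10


class TestFullPipeline:
    def test_duplicate_snp_columns_get_identical_statistics(self, small_config, small_study):
        X, Z, y = small_study.pooled()
        X_dup = np.column_stack([X, X[:, 5]]).astype(np.int8)
        snps = None
        res = run_plaintext_gwas(X_dup, Z, y, small_config)
        kept = np.flatnonzero(res.keep_mask)
        if res.keep_mask[5] and res.keep_mask[-1]:
            table = res.table.set_index(
                np.flatnonzero(res.keep_mask)
            )
            assert table.loc[5, "chisq"] == pytest.approx(table.loc[X.shape[1], "chisq"], rel=1e-9)

    def test_planted_large_effect_snp_ranks_first(self):
        cfg = PipelineConfig(
            simulation=SimulationConfig(
                n_samples=600, n_snps=300, n_covariates=1, n_nodes=1,
                n_causal=1, heritability=0.3, missing_rate=0.0, seed=21,
            ),
            grid=GridConfig(n_folds=4, n_penalties=3, block_size=100),
            seed=21,
        )
        study = simulate_study(cfg.simulation)
        X, Z, y = study.pooled()
        res = run_plaintext_gwas(X, Z, y, cfg, snps=study.snps)
        causal_id = study.snps["snp_id"].iloc[study.causal_idx[0]]
        top = res.table.sort_values("chisq", ascending=False).iloc[0]
        assert top["snp_id"] == causal_id
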