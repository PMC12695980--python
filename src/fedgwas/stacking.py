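"""Centralized stacked ridge regression GWAS (the plaintext oracle).

Two levels of ridge regression in a K-fold cross-validation frame:

* Level 0 fits, for each vertical SNP block b and ridge penalty lambda_r, a
  ridge estimator on the folds excluding k and predicts fold k, producing the
  N x (B*R) out-of-fold feature matrix W.
* Level 1 ridge-regresses the phenotype on W (penalties omega_r = (BR/M)
  lambda_r), selects r* by the summed out-of-fold residual sum of squares,
  and assembles the whole-genome predictor y_hat.

The association statistic for a projected, standardized test SNP x is
chi2 = (x^T (y~ - y_hat))^2 / (sigma2 * x^T x) with 1 degree of freedom and
sigma2 = ||y~ - y_hat||^2 / (N - C), C counting the intercept-augmented
covariate columns.  This module is also the ground truth against which every
distributed stage is verified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import GridConfig, PipelineConfig, QcThresholds
from . import qc as qc_mod
from .encoding import SharedSeed, fold_assignment
from .projection import project_covariates_plaintext


@dataclass
class RidgeGrid:
    """Heritability grid h_r and the induced Level-0/Level-1 penalties."""

    h: np.ndarray
    lambdas: np.ndarray
    omegas: np.ndarray
    n_snps: int
    n_blocks: int

    @property
    def R(self) -> int:
        return len(self.h)


def build_ridge_grid(n_snps: int, n_blocks: int, n_penalties: int) -> RidgeGrid:
    """h_r linear on [0.01, 0.99]; lambda_r = M (1-h^2)/h^2; omega_r = (BR/M) lambda_r."""
    if n_penalties < 2:
        raise ValueError("need at least two ridge parameters")
    if n_snps < 1 or n_blocks < 1:
        raise ValueError("n_snps and n_blocks must be positive")
    R = n_penalties
    r = np.arange(1, R + 1)
    h = (0.01 * (R - 1) + 0.98 * (r - 1)) / (R - 1)
    lam = n_snps * (1.0 - h**2) / h**2
    omega = (n_blocks * R / n_snps) * lam
    return RidgeGrid(h=h, lambdas=lam, omegas=omega, n_snps=n_snps, n_blocks=n_blocks)


def make_blocks(n_snps: int, block_size: int) -> list[tuple[int, int]]:
    """Contiguous vertical blocks [(start, stop), ...]; last holds the remainder."""
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    return [(s, min(s + block_size, n_snps)) for s in range(0, n_snps, block_size)]


def _ridge_solve_grid(G: np.ndarray, c: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Solve (G + lam I) beta = c for every lam via one eigendecomposition."""
    w, V = np.linalg.eigh(G)
    Vc = V.T @ c
    return np.stack([V @ (Vc / (w + lam)) for lam in lambdas], axis=1)


def level0_fit_predict(
    X: np.ndarray,
    y: np.ndarray,
    folds: np.ndarray,
    grid: RidgeGrid,
    blocks: list[tuple[int, int]],
    n_folds: int | None = None,
) -> np.ndarray:
    """Out-of-fold Level-0 predictions W, columns ordered block-major then penalty."""
    N = X.shape[0]
    B, R = len(blocks), grid.R
    if n_folds is not None and any((folds == k).sum() == 0 for k in range(n_folds)):
        raise ValueError("empty fold")
    fold_ids = np.unique(folds)
    W = np.zeros((N, B * R))
    for k in fold_ids:
        test = folds == k
        train = ~test
        y_tr = y[train]
        for b, (s, e) in enumerate(blocks):
            Xb_tr = X[train, s:e]
            G = Xb_tr.T @ Xb_tr
            c = Xb_tr.T @ y_tr
            betas = _ridge_solve_grid(G, c, grid.lambdas)  # [Nb x R]
            W[np.ix_(test, np.arange(b * R, b * R + R))] = X[test, s:e] @ betas
    return W


@dataclass
class Level1Fit:
    eta: dict        # fold k -> [B*R x R] per-penalty coefficients
    r_star: int
    y_hat: np.ndarray
    rss: np.ndarray  # summed out-of-fold RSS per penalty


def level1_fit(W: np.ndarray, y: np.ndarray, folds: np.ndarray, grid: RidgeGrid) -> Level1Fit:
    """Per-fold Level-1 ridge fits, penalty selection and the global predictor."""
    fold_ids = np.unique(folds)
    R = grid.R
    rss = np.zeros(R)
    eta_all: dict = {}
    preds: dict = {}
    for k in fold_ids:
        test = folds == k
        train = ~test
        Wtr, ytr = W[train], y[train]
        etas = _ridge_solve_grid(Wtr.T @ Wtr, Wtr.T @ ytr, grid.omegas)  # [BR x R]
        eta_all[int(k)] = etas
        pred = W[test] @ etas  # [n_k x R]
        rss += ((y[test, None] - pred) ** 2).sum(axis=0)
        preds[int(k)] = pred
    r_star = int(np.argmin(rss))  # argmin; ties break toward the smallest r
    y_hat = np.zeros(len(y))
    for k in fold_ids:
        y_hat[folds == k] = preds[int(k)][:, r_star]
    return Level1Fit(eta=eta_all, r_star=r_star, y_hat=y_hat, rss=rss)


def chi2_test(
    X_test: np.ndarray,
    y_proj: np.ndarray,
    y_hat: np.ndarray,
    n_covariate_cols: int,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Vectorized 1-df association test for the columns of X_test.

    n_covariate_cols counts the columns of the intercept-augmented covariate
    matrix (the rank removed by projection).
    """
    res = y_proj - y_hat
    N = len(y_proj)
    dof = N - n_covariate_cols
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = float(res @ res) / dof
    xtx = np.einsum("ij,ij->j", X_test, X_test)
    if (xtx == 0).any():
        raise ValueError("null test vector (x~^T x~ = 0)")
    chisq = (X_test.T @ res) ** 2 / (sigma2 * xtx)
    pvals = stats.chi2.sf(chisq, df=1)
    return chisq, pvals, sigma2


@dataclass
class GwasResult:
    """Association table plus the intermediates tests care about."""

    table: pd.DataFrame
    keep_mask: np.ndarray
    qc_report: pd.DataFrame
    r_star: int
    sigma2: float
    fold_labels: np.ndarray


def run_plaintext_gwas(
    genotypes: np.ndarray,
    covariates: np.ndarray,
    phenotype: np.ndarray,
    config: PipelineConfig | None = None,
    snps: pd.DataFrame | None = None,
) -> GwasResult:
    """QC -> projection/standardization -> Level 0 -> Level 1 -> per-SNP test."""
    config = config or PipelineConfig()
    grid_cfg: GridConfig = config.grid
    thresholds: QcThresholds = config.qc

    counts = qc_mod.local_counts(genotypes)
    snp_ids = snps["snp_id"].to_numpy() if snps is not None else None
    report, keep = qc_mod.apply_filters(counts, thresholds, snp_ids=snp_ids)
    if not keep.any():
        raise ValueError("no SNPs survive QC")

    kept = qc_mod.SnpCounts.from_matrix(counts.as_matrix()[keep])
    X_proj, y_proj, n_cov_cols = project_covariates_plaintext(
        genotypes[:, keep], covariates, phenotype, counts=kept
    )

    N, M = X_proj.shape
    seed = SharedSeed(config.seed)
    folds = fold_assignment(seed, N, grid_cfg.n_folds)
    blocks = make_blocks(M, grid_cfg.block_size)
    grid = build_ridge_grid(M, len(blocks), grid_cfg.n_penalties)

    W = level0_fit_predict(X_proj, y_proj, folds, grid, blocks, n_folds=grid_cfg.n_folds)
    fit = level1_fit(W, y_proj, folds, grid)
    chisq, pvals, sigma2 = chi2_test(X_proj, y_proj, fit.y_hat, n_cov_cols)

    if snps is not None:
        meta = snps.loc[keep, ["snp_id", "chrom", "pos"]].reset_index(drop=True)
    else:
        meta = pd.DataFrame(
            {"snp_id": [f"snp{j}" for j in np.flatnonzero(keep)],
             "chrom": 1, "pos": np.flatnonzero(keep) + 1}
        )
    table = meta.assign(
        chisq=chisq,
        p=pvals,
        maf=report.loc[keep, "maf"].to_numpy(),
        missing_rate=report.loc[keep, "missing_rate"].to_numpy(),
        hwe_chisq=report.loc[keep, "hwe_chisq"].to_numpy(),
        significant=pvals < config.significance_p,
    )
    return GwasResult(
        table=table,
        keep_mask=keep,
        qc_report=report,
        r_star=fit.r_star,
        sigma2=sigma2,
        fold_labels=folds,
    )
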