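"""Covariate projection and standardization, plaintext and encoded.

The model projects genotypes and phenotype onto the null space of the
intercept-augmented covariate matrix Z1 = [Z | 1]:

    X~ = (I - Z1 (Z1^T Z1)^{-1} Z1^T) X S_X,

with S_X = diag(1/sd_j) from count-derived population moments, and likewise
y~ = P y / s_y.  Appending the all-ones column makes the projection also
mean-center every column, so standardization and covariate removal happen in
a single computation.

In the distributed setting each node holds a horizontal row-slice of X, Z, y.
The node encodes its slice two-sidedly with shared-seed orthonormal-column
obfuscation matrices (the left matrix O_Z is one global (N+k) x N matrix of
which a node uses the column slice for its sample range), the server combines
the encoded pieces linearly (no decode possible without the seed), and each
node decodes its own projected slice exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import qc as qc_mod
from .encoding import (
    ObfuscationMatrix,
    PhenotypeDecoy,
    SharedSeed,
    draw_pad,
    make_decoy,
    pad_and_permute,
    shared_obfuscation,
    unpermute,
)
from .simulate import MISSING

_RANK_RCOND = 1e-10


def impute_and_standardize_stats(
    genotypes: np.ndarray, counts: qc_mod.SnpCounts | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Float dosage matrix with missing entries mean-imputed, plus (mean, sd).

    When counts are given, the moments come from the pooled genotype counts
    (the quantities the masked-sum stage aggregates); otherwise they are
    computed directly.
    """
    X = np.asarray(genotypes, dtype=float).copy()
    miss = np.asarray(genotypes) == MISSING
    if counts is not None:
        mean, sd = qc_mod.standardization_from_counts(counts)
    else:
        Xm = np.where(miss, np.nan, X)
        mean = np.nanmean(Xm, axis=0)
        sd = np.nanstd(Xm, axis=0)
        if (sd == 0).any():
            raise ValueError("zero-variance column; run QC first")
    X[miss] = np.broadcast_to(mean, X.shape)[miss]
    return X, mean, sd


def intercept_augment(Z: np.ndarray) -> np.ndarray:
    return np.column_stack([Z, np.ones(Z.shape[0])])


def _check_rank(Z1: np.ndarray) -> None:
    s = np.linalg.svd(Z1, compute_uv=False)
    if s[-1] <= s[0] * _RANK_RCOND:
        # name the offending columns for the error message
        bad = []
        for j in range(Z1.shape[1] - 1):
            others = np.delete(Z1, j, axis=1)
            resid = Z1[:, j] - others @ np.linalg.lstsq(others, Z1[:, j], rcond=None)[0]
            if np.linalg.norm(resid) <= 1e-8 * max(1.0, np.linalg.norm(Z1[:, j])):
                bad.append(j)
        raise ValueError(f"covariate matrix is rank deficient (collinear columns: {bad})")


def project_out(Z1: np.ndarray, A: np.ndarray) -> np.ndarray:
    """(I - Z1 (Z1^T Z1)^{-1} Z1^T) A via a small normal-equations solve."""
    return A - Z1 @ np.linalg.solve(Z1.T @ Z1, Z1.T @ A)


def project_covariates_plaintext(
    genotypes: np.ndarray,
    covariates: np.ndarray,
    phenotype: np.ndarray,
    counts: qc_mod.SnpCounts | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Oracle path: projected/standardized X~ and y~ plus the projector rank.

    Returns (X_proj [N x M], y_proj [N], number of Z1 columns).
    """
    X, _, sd = impute_and_standardize_stats(genotypes, counts)
    Z1 = intercept_augment(np.asarray(covariates, dtype=float))
    _check_rank(Z1)
    y = np.asarray(phenotype, dtype=float)
    s_y = float(np.std(y))
    if s_y == 0:
        raise ValueError("constant phenotype (zero standard deviation)")
    X_proj = project_out(Z1, X) / sd
    y_proj = project_out(Z1, y[:, None])[:, 0] / s_y
    return X_proj, y_proj, Z1.shape[1]


# ---------------------------------------------------------------------------
# encoded path


@dataclass
class ProjectionEncoders:
    """Shared-seed material for the projection stage (node-side only)."""

    o_z: ObfuscationMatrix       # (N+kz) x N, global; nodes use column slices
    o_zp: ObfuscationMatrix      # (C+1+kz') x (C+1)
    o_x: ObfuscationMatrix       # (M+kx) x M
    o_y: ObfuscationMatrix       # (1+k_my+ky) x (1+k_my)
    decoy: PhenotypeDecoy        # N-row decoy block, permutation, sign


def make_projection_encoders(seed: SharedSeed, n_samples: int, n_cov_cols: int, n_snps: int) -> ProjectionEncoders:
    pads = seed.child("proj_pads")
    o_z = shared_obfuscation(seed, ("proj_oz",), n_samples, draw_pad(pads))
    o_zp = shared_obfuscation(seed, ("proj_ozp",), n_cov_cols, draw_pad(pads))
    o_x = shared_obfuscation(seed, ("proj_ox",), n_snps, draw_pad(pads))
    k_my = draw_pad(pads, 2, 8)
    o_y = shared_obfuscation(seed, ("proj_oy",), 1 + k_my, draw_pad(pads))
    decoy = make_decoy(seed, n_samples, k_my)
    return ProjectionEncoders(o_z=o_z, o_zp=o_zp, o_x=o_x, o_y=o_y, decoy=decoy)


def encode_for_projection(
    enc: ProjectionEncoders,
    X_p: np.ndarray,
    Z_p: np.ndarray,
    y_p: np.ndarray,
    offset: int,
) -> dict[str, np.ndarray]:
    """One node's three encoded payloads for the projection stage.

    X_p must already be mean-imputed (raw dosage scale: the S_X scaling is
    applied after decoding, as the final step of the decode expression).
    """
    n_p = X_p.shape[0]
    rows = np.arange(offset, offset + n_p)
    oz_slice = enc.o_z.slice_columns(rows)
    Z1_p = intercept_augment(np.asarray(Z_p, dtype=float))
    payload_z = oz_slice @ Z1_p @ enc.o_zp.matrix.T
    payload_x = oz_slice @ np.asarray(X_p, dtype=float) @ enc.o_x.matrix.T
    padded_y = pad_and_permute(np.asarray(y_p, dtype=float), enc.decoy, rows=rows)
    payload_y = oz_slice @ padded_y @ enc.o_y.matrix.T
    return {"proj_Z": payload_z, "proj_X": payload_x, "proj_y": payload_y}


def server_projection(
    payloads_z: list[np.ndarray],
    payloads_x: list[np.ndarray],
    payloads_y: list[np.ndarray],
    n_cov_cols: int | None = None,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Server side of the encoded projection.

    With T = sum_p O_Z Z1_p O_Z'^T the server forms, for each node,
    payload - (O_Z Z1_p O_Z'^T) T^+ sum_q payload_q, which is the encoded
    image of the plaintext projection.  T^+ is the pseudo-inverse (the padded
    T is rank C+1 by construction).
    """
    T = sum(payloads_z)
    rank = np.linalg.matrix_rank(T, tol=None)
    if n_cov_cols is not None and rank < n_cov_cols:
        raise ValueError(
            f"covariate payload rank {rank} < expected {n_cov_cols}: collinear pooled covariates; aborting"
        )
    T_pinv = np.linalg.pinv(T, rcond=_RANK_RCOND)
    total_x = sum(payloads_x)
    total_y = sum(payloads_y)
    proj_x = T_pinv @ total_x
    proj_y = T_pinv @ total_y
    out_x = [bx - az @ proj_x for bx, az in zip(payloads_x, payloads_z)]
    out_y = [by - az @ proj_y for by, az in zip(payloads_y, payloads_z)]
    return out_x, out_y


def decode_projection(
    enc: ProjectionEncoders,
    result_x: np.ndarray,
    result_y: np.ndarray,
    offset: int,
    n_p: int,
    sd: np.ndarray,
    s_y: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Node-side decode: exact recovery of the projected, standardized slice."""
    rows = np.arange(offset, offset + n_p)
    oz_slice = enc.o_z.slice_columns(rows)
    X_proj = (oz_slice.T @ result_x @ enc.o_x.matrix) / sd
    padded = oz_slice.T @ result_y @ enc.o_y.matrix
    y_proj = unpermute(padded, enc.decoy) / s_y
    return X_proj, y_proj
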