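"""Iterative solvers for the distributed ridge stages.

Both solvers operate purely on linear-algebra objects that are already in
the encoded (obfuscated) coordinate system; neither needs to know whether a
basis change was applied, because both are exactly covariant under
orthonormal-column conjugation.

* ``consensus_admm_ridge`` solves
      min_{beta_p, z} 1/2 sum_p ||X_p beta_p - y_p||^2 + lam/2 ||z||^2,
      s.t. beta_p = z,
  given only each node's inverted regularized Gram (G_p + ell I)^{-1} and
  cross-product c_p = X_p^T y_p (encoded).  Gauss-Seidel order: per-node
  primal update, consensus (z) update, dual update, with over-relaxation.
* ``conjugate_gradient_ridge`` solves (W + omega I) x = b for a PSD Gram W.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class AdmmResult:
    z: np.ndarray
    n_iter: int
    primal_residual: float
    dual_residual: float
    converged: bool


def admm_penalty_default(lam: float, n_train: int, n_nodes: int) -> float:
    """Consensus penalty heuristic: geometric mean of the ridge penalty and
    the per-node data scale (standardized columns have squared norm ~ rows),
    floored at the ridge penalty's own scale."""
    data_scale = max(1.0, n_train / max(1, n_nodes))
    return float(np.sqrt(lam * (lam + data_scale)))


def consensus_admm_ridge(
    inv_grams: list[np.ndarray],
    cross: list[np.ndarray],
    lam: float,
    penalty: float,
    max_iter: int = 500,
    tol: float = 1e-11,
    over_relax: float = 1.7,
) -> AdmmResult:
    """Iterate to the global ridge solution from per-node pieces.

    inv_grams[p] must equal (G_p + penalty I)^{-1} (possibly conjugated by a
    shared orthonormal-column matrix); cross[p] the matching X_p^T y_p.
    Stopping is on relative primal and dual residual norms.
    """
    P = len(inv_grams)
    d = cross[0].shape[0]
    z = np.zeros(d)
    duals = [np.zeros(d) for _ in range(P)]
    ell = float(penalty)
    alpha = float(over_relax)
    primal = dual = np.inf
    # the iteration's floating-point noise floor sits near eps * ||dual|| /
    # ||primal||; track the best iterate and stop when progress stalls there
    best = np.inf
    best_z = z
    best_it = 0
    since_improved = 0
    stall_accept = max(tol, 1e-7)
    for it in range(1, max_iter + 1):
        z_prev = z
        betas = [R @ (c + ell * z - u) for R, c, u in zip(inv_grams, cross, duals)]
        relaxed = [alpha * b + (1.0 - alpha) * z_prev for b in betas]
        z = (ell * sum(relaxed) + sum(duals)) / (lam + P * ell)
        duals = [u + ell * (b - z) for u, b in zip(duals, relaxed)]
        primal = np.sqrt(sum(float(np.sum((b - z) ** 2)) for b in betas))
        dual = ell * np.sqrt(P) * float(np.linalg.norm(z - z_prev))
        scale_p = max(
            np.sqrt(sum(float(np.sum(b**2)) for b in betas)),
            np.sqrt(P) * float(np.linalg.norm(z)),
            1e-300,
        )
        scale_d = max(np.sqrt(sum(float(np.sum(u**2)) for u in duals)), 1e-300)
        rel = max(primal / scale_p, dual / scale_d)
        if rel <= tol:
            return AdmmResult(z=z, n_iter=it, primal_residual=primal, dual_residual=dual, converged=True)
        if rel < 0.5 * best:
            best, best_z, best_it, since_improved = rel, z, it, 0
        else:
            since_improved += 1
            if since_improved >= 30 and best <= stall_accept:
                return AdmmResult(
                    z=best_z, n_iter=it, primal_residual=primal, dual_residual=dual, converged=True
                )
    converged = best <= stall_accept
    return AdmmResult(
        z=best_z if converged else z,
        n_iter=max_iter,
        primal_residual=primal,
        dual_residual=dual,
        converged=converged,
    )


@dataclass
class CgResult:
    x: np.ndarray
    n_iter: int
    residual_norm: float


def conjugate_gradient_ridge(
    gram: np.ndarray,
    omega: float,
    rhs: np.ndarray,
    max_iter: int | None = None,
    tol: float = 1e-13,
) -> CgResult:
    """Standard CG on (gram + omega I) x = rhs; exact in <= dim steps."""
    d = len(rhs)
    cap = min(max_iter or 2 * d, 10 * d)
    x = np.zeros(d)
    resid = rhs.copy()
    direction = resid.copy()
    rs = float(resid @ resid)
    b_norm = max(float(np.linalg.norm(rhs)), 1e-300)
    it = 0
    while it < cap and np.sqrt(rs) > tol * b_norm:
        a = gram @ direction + omega * direction
        gamma = rs / float(direction @ a)
        x = x + gamma * direction
        resid = resid - gamma * a
        rs_new = float(resid @ resid)
        direction = resid + (rs_new / rs) * direction
        rs = rs_new
        it += 1
    return CgResult(x=x, n_iter=it, residual_norm=float(np.sqrt(rs)))
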