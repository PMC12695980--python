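"""The central-server role: blind aggregation and solving on encoded data.

The server never holds the shared seed.  It relays masked sums, combines the
obfuscated projection payloads, runs the Level-0 consensus-ADMM solves and
the Level-1 conjugate-gradient solves entirely in the encoded coordinate
system, evaluates the per-SNP chi-square statistics from encoded test
vectors, and returns the results.  Because every encoding has exactly
orthonormal columns, each encoded solve is the centralized computation
conjugated by an unknown basis — the server's arithmetic is exact while its
view stays padded and masked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ..config import PipelineConfig
from ..projection import server_projection
from ..solvers import admm_penalty_default, consensus_admm_ridge, conjugate_gradient_ridge
from ..stacking import build_ridge_grid, make_blocks
from ..transport import Endpoint
from . import messages as msg


@dataclass
class ServerResult:
    chisq: np.ndarray
    pvals: np.ndarray
    r_star: int
    sigma2: float
    admm_iterations: list = field(default_factory=list)
    cg_iterations: list = field(default_factory=list)


@dataclass
class ServerRole:
    n_nodes: int
    n_samples_total: int
    n_cov_cols: int          # C + 1 (intercept-augmented)
    config: PipelineConfig

    def run(self, ep: Endpoint) -> ServerResult:
        P = self.n_nodes
        N = self.n_samples_total
        nodes = [f"node{p}" for p in range(P)]

        # --- masked aggregation rounds -------------------------------------
        counts = [ep.receive(n).payload for n in nodes]
        total = sum(counts)
        for n in nodes:
            ep.send(n, msg.STAGE_QC, msg.SUM_COUNTS, total)
        moments = [ep.receive(n).payload for n in nodes]
        mtotal = sum(moments)
        for n in nodes:
            ep.send(n, msg.STAGE_MOMENTS, msg.SUM_MOMENTS, mtotal)
        dims = [ep.receive(n).payload for n in nodes]
        m_kept = int(dims[0][0])
        if any(int(d[0]) != m_kept for d in dims):
            raise ValueError("nodes disagree on the retained SNP count")

        # --- projection -----------------------------------------------------
        pz, px, py = [], [], []
        for n in nodes:
            pz.append(ep.receive(n).payload)
            px.append(ep.receive(n).payload)
            py.append(ep.receive(n).payload)
        out_x, out_y = server_projection(pz, px, py, n_cov_cols=self.n_cov_cols)
        for n, ox, oy in zip(nodes, out_x, out_y):
            ep.send(n, msg.STAGE_PROJECTION, msg.PROJ_X_RESULT, ox)
            ep.send(n, msg.STAGE_PROJECTION, msg.PROJ_Y_RESULT, oy)
        del pz, px, py, out_x, out_y

        # --- Level 0: consensus ADMM per (fold, block, penalty) -------------
        gcfg, solver = self.config.grid, self.config.solver
        K, R = gcfg.n_folds, gcfg.n_penalties
        blocks = make_blocks(m_kept, gcfg.block_size)
        B = len(blocks)
        grid = build_ridge_grid(m_kept, B, R)
        n_train_pub = round(N * (K - 1) / K)

        pheno = [[ep.receive(n).payload for k in range(K)] for n in nodes]  # [p][k]
        pheno_sum = [sum(pheno[p][k] for p in range(P)) for k in range(K)]

        w_enc = [np.zeros((len(pheno_sum[k]), B * R)) for k in range(K)]
        admm_iters = []
        for b in range(B):
            for r in range(R):
                lam = float(grid.lambdas[r])
                ell = admm_penalty_default(lam, n_train_pub, P)
                designs = []   # [p][k]
                grams = []
                for p, n in enumerate(nodes):
                    designs.append([ep.receive(n).payload for k in range(K)])
                    grams.append([ep.receive(n).payload for k in range(K)])
                # per-node cross-products over the training folds
                t = [[designs[p][k].T @ pheno[p][k] for k in range(K)] for p in range(P)]
                t_tot = [sum(t[p]) for p in range(P)]
                for k in range(K):
                    rhs = [t_tot[p] - t[p][k] for p in range(P)]
                    res = consensus_admm_ridge(
                        [grams[p][k] for p in range(P)],
                        rhs,
                        lam=lam,
                        penalty=ell,
                        max_iter=solver.admm_max_iter,
                        tol=solver.admm_tol,
                        over_relax=solver.admm_over_relax,
                    )
                    if not res.converged:
                        raise RuntimeError(
                            f"ADMM did not converge (block {b}, penalty {r}, fold {k}): "
                            f"primal {res.primal_residual:.2e}, dual {res.dual_residual:.2e}"
                        )
                    admm_iters.append(res.n_iter)
                    w_enc[k][:, b * R + r] = sum(designs[p][k] @ res.z for p in range(P))
                del designs, grams

        # --- Level 1: CG ridge on the encoded feature matrix ----------------
        gram_k = [w_enc[k].T @ w_enc[k] for k in range(K)]
        rhs_k = [w_enc[k].T @ pheno_sum[k] for k in range(K)]
        gram_tot = sum(gram_k)
        rhs_tot = sum(rhs_k)
        cg_iters = []
        eta = {}
        rss = np.zeros(R)
        for k in range(K):
            for r in range(R):
                res = conjugate_gradient_ridge(
                    gram_tot - gram_k[k],
                    float(grid.omegas[r]),
                    rhs_tot - rhs_k[k],
                    max_iter=solver.cg_max_iter,
                    tol=solver.cg_tol,
                )
                cg_iters.append(res.n_iter)
                eta[(k, r)] = res.x
                rss[r] += float(np.sum((pheno_sum[k] - w_enc[k] @ res.x) ** 2))
        r_star = int(np.argmin(rss))

        residual = [pheno_sum[k] - w_enc[k] @ eta[(k, r_star)] for k in range(K)]
        dof = N - self.n_cov_cols
        sigma2 = sum(float(np.sum(rk**2)) for rk in residual) / dof

        # --- association ----------------------------------------------------
        numer = np.zeros(m_kept)
        denom = np.zeros(m_kept)
        for k in range(K):
            u_sum = None
            for n in nodes:
                u = ep.receive(n).payload
                denom += np.einsum("ij,ij->j", u, u)
                u_sum = u if u_sum is None else u_sum + u
            numer += u_sum.T @ residual[k]
        if (denom == 0).any():
            raise ValueError("null encoded test vector (zero denominator)")
        chisq = numer**2 / (sigma2 * denom)
        pvals = stats.chi2.sf(chisq, df=1)
        for n in nodes:
            ep.send(n, msg.STAGE_RESULT, msg.RESULT_CHISQ, chisq)
        return ServerResult(
            chisq=chisq,
            pvals=pvals,
            r_star=r_star,
            sigma2=sigma2,
            admm_iterations=admm_iters,
            cg_iterations=cg_iters,
        )
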