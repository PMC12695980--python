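"""The computational-node role of the distributed pipeline.

A node holds one horizontal slice (X_p, Z_p, y_p) plus its global sample
offset and the shared secret seed.  It participates in five stages:

A/B. masked-count aggregation (QC and standardization moments),
C.   two-sided obfuscated covariate projection,
D.   Level-0 payloads (inverted regularized Grams, encoded design operators,
     encoded fold phenotypes) for the server's consensus-ADMM solves,
F.   encoded per-SNP test vectors, then receipt of the chi-square table.

Everything random is derived from (shared seed, stage path); the server is
never sent the seed or any object derived from it in the clear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .. import projection, qc as qc_mod
from ..config import PipelineConfig
from ..encoding import (
    SharedSeed,
    draw_pad,
    fold_assignment,
    make_masks,
    shared_obfuscation,
)
from ..solvers import admm_penalty_default
from ..stacking import build_ridge_grid, make_blocks
from ..transport import SERVER, Endpoint
from . import messages as msg


@dataclass
class NodeResult:
    chisq: np.ndarray
    pvals: np.ndarray
    keep_mask: np.ndarray
    qc_report: object
    fold_labels: np.ndarray


@dataclass
class NodeRole:
    party_id: str
    index: int               # p in 0..P-1
    genotypes: np.ndarray    # int8 dosages, -1 missing
    covariates: np.ndarray
    phenotype: np.ndarray
    offset: int              # samples added to the study before this node
    n_samples_total: int
    n_nodes: int
    seed: SharedSeed
    config: PipelineConfig

    def run(self, ep: Endpoint) -> NodeResult:
        P = self.n_nodes
        N = self.n_samples_total
        n_p = self.genotypes.shape[0]
        m_total = self.genotypes.shape[1]

        # --- stage A/B: QC via masked counts -------------------------------
        counts = qc_mod.local_counts(self.genotypes)
        masks = make_masks(self.seed, ("qc_counts",), (m_total, 4), P, integer=True)
        ep.send(SERVER, msg.STAGE_QC, msg.MASKED_COUNTS, counts.as_matrix() + masks.masks[self.index])
        total = ep.receive(SERVER).payload
        pooled = qc_mod.SnpCounts.from_matrix(total - masks.total)
        report, keep = qc_mod.apply_filters(pooled, self.config.qc)
        if not keep.any():
            raise ValueError("no SNPs survive QC")
        m_kept = int(keep.sum())
        kept_counts = qc_mod.SnpCounts.from_matrix(pooled.as_matrix()[keep])

        # phenotype moments via masked sums
        y = np.asarray(self.phenotype, dtype=float)
        mmasks = make_masks(self.seed, ("moments",), (2,), P, integer=False)
        payload = np.array([y.sum(), (y**2).sum()]) + mmasks.masks[self.index]
        ep.send(SERVER, msg.STAGE_MOMENTS, msg.MASKED_MOMENTS, payload)
        mom = ep.receive(SERVER).payload - mmasks.total
        var_y = mom[1] / N - (mom[0] / N) ** 2
        if var_y <= 0:
            raise ValueError("constant phenotype (zero standard deviation)")
        s_y = float(np.sqrt(var_y))

        # study-level dimensions the server is allowed to know
        ep.send(SERVER, msg.STAGE_QC, msg.PUBLIC_DIMS, np.array([m_kept], dtype=np.int64))

        # --- stage C: obfuscated covariate projection ----------------------
        mean, sd = qc_mod.standardization_from_counts(kept_counts)
        X_imp, _, _ = projection.impute_and_standardize_stats(self.genotypes[:, keep], kept_counts)
        n_cov_cols = self.covariates.shape[1] + 1
        enc = projection.make_projection_encoders(self.seed, N, n_cov_cols, m_kept)
        payloads = projection.encode_for_projection(enc, X_imp, self.covariates, y, self.offset)
        ep.send(SERVER, msg.STAGE_PROJECTION, msg.PROJ_Z, payloads["proj_Z"])
        ep.send(SERVER, msg.STAGE_PROJECTION, msg.PROJ_X, payloads["proj_X"])
        ep.send(SERVER, msg.STAGE_PROJECTION, msg.PROJ_Y, payloads["proj_y"])
        res_x = ep.receive(SERVER).payload
        res_y = ep.receive(SERVER).payload
        X_t, y_t = projection.decode_projection(enc, res_x, res_y, self.offset, n_p, sd, s_y)
        del X_imp, payloads, res_x, res_y

        # --- stage D: Level-0 payloads -------------------------------------
        gcfg = self.config.grid
        K, R = gcfg.n_folds, gcfg.n_penalties
        labels = fold_assignment(self.seed, N, K)
        blocks = make_blocks(m_kept, gcfg.block_size)
        B = len(blocks)
        grid = build_ridge_grid(m_kept, B, R)
        sign = self._l0_sign()

        fold_rows: list[np.ndarray] = []   # local row indices per fold
        fold_pos: list[np.ndarray] = []    # positions of those rows within the global fold
        o_y = []
        for k in range(K):
            members = np.flatnonzero(labels == k)
            mine = (members >= self.offset) & (members < self.offset + n_p)
            if not mine.any():
                raise ValueError(f"node {self.party_id} has no samples in fold {k}")
            fold_rows.append(members[mine] - self.offset)
            fold_pos.append(np.flatnonzero(mine))
            pad = draw_pad(self.seed.child("level0_pads", "fold", k))
            o_y.append(shared_obfuscation(self.seed, ("level0_oy", "fold", k), len(members), pad))

        for k in range(K):
            ep.send(
                SERVER, msg.STAGE_LEVEL0, msg.L0_PHENO,
                o_y[k].slice_columns(fold_pos[k]) @ y_t[fold_rows[k]],
            )

        n_train_pub = round(N * (K - 1) / K)
        for b, (s, e) in enumerate(blocks):
            Xb = X_t[:, s:e]
            n_b = e - s
            g_all = Xb.T @ Xb
            g_folds = [Xb[fold_rows[k]].T @ Xb[fold_rows[k]] for k in range(K)]
            for r in range(R):
                pad = draw_pad(self.seed.child("level0_pads", "block", b, "penalty", r))
                o_x = shared_obfuscation(self.seed, ("level0_ox", "block", b, "penalty", r), n_b, pad)
                ell = admm_penalty_default(grid.lambdas[r], n_train_pub, P)
                Q = Xb @ o_x.matrix.T  # [n_p x (n_b + pad)]
                for k in range(K):
                    ep.send(
                        SERVER, msg.STAGE_LEVEL0, msg.L0_DESIGN,
                        sign * (o_y[k].slice_columns(fold_pos[k]) @ Q[fold_rows[k]]),
                    )
                for k in range(K):
                    g_train = g_all - g_folds[k]
                    inv = np.linalg.inv(g_train + ell * np.eye(n_b))
                    ep.send(
                        SERVER, msg.STAGE_LEVEL0, msg.L0_GRAM,
                        o_x.matrix @ inv @ o_x.matrix.T,
                    )

        # --- stage F: association ------------------------------------------
        if self.config.shuffle_snps:
            perm = self.seed.child("assoc_shuffle").permutation(m_kept)
        else:
            perm = np.arange(m_kept)
        for k in range(K):
            ep.send(
                SERVER, msg.STAGE_ASSOCIATION, msg.ASSOC_TEST,
                o_y[k].slice_columns(fold_pos[k]) @ X_t[np.ix_(fold_rows[k], perm)],
            )
        chisq_shuffled = ep.receive(SERVER).payload
        # position j of the payload is SNP perm[j]; undo the optional shuffle
        chisq = np.empty(m_kept)
        chisq[perm] = chisq_shuffled
        pvals = stats.chi2.sf(chisq, df=1)
        return NodeResult(
            chisq=chisq,
            pvals=pvals,
            keep_mask=keep,
            qc_report=report,
            fold_labels=labels,
        )

    def _l0_sign(self) -> float:
        return float(self.seed.child("level0_sign").choice([-1.0, 1.0]))
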