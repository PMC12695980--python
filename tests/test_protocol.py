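"""Distributed protocol: oracle equivalence, invariances, privacy audit."""

import numpy as np
import pytest

from fedgwas import (
    PipelineConfig,
    SimulationConfig,
    neglog10_r2,
    run_federated_gwas,
    run_plaintext_gwas,
    simulate_study,
)
from fedgwas.config import GridConfig
from fedgwas.protocol import messages as msg
from fedgwas.simulate import MISSING, SimulatedStudy, partition_across_nodes
from fedgwas.transport import row_digest


@pytest.fixture(scope="module")
def fed_and_plain(small_config_module, small_study_module):
    fed = run_federated_gwas(small_study_module, small_config_module)
    X, Z, y = small_study_module.pooled()
    plain = run_plaintext_gwas(X, Z, y, small_config_module, snps=small_study_module.snps)
    return fed, plain


@pytest.fixture(scope="module")
def small_config_module():
    return PipelineConfig(
        simulation=SimulationConfig(
            n_samples=300, n_snps=120, n_covariates=2, n_nodes=3,
            n_causal=5, heritability=0.4, seed=7,
        ),
        grid=GridConfig(n_folds=3, n_penalties=3, block_size=40),
        seed=7,
    )


@pytest.fixture(scope="module")
def small_study_module(small_config_module):
    return simulate_study(small_config_module.simulation)


class TestOracleEquivalence:
    def test_qc_decisions_identical(self, fed_and_plain):
        fed, plain = fed_and_plain
        assert np.array_equal(fed.keep_mask, plain.keep_mask)

    def test_chisq_matches_plaintext(self, fed_and_plain):
        fed, plain = fed_and_plain
        c_f = fed.table["chisq"].to_numpy()
        c_p = plain.table["chisq"].to_numpy()
        # mixed tolerance: relative on real signals, absolute near zero
        assert (np.abs(c_f - c_p) / (1.0 + c_p)).max() < 1e-6

    def test_neglog10_p_correlation(self, fed_and_plain):
        fed, plain = fed_and_plain
        assert neglog10_r2(fed.table["p"], plain.table["p"]) >= 0.999999

    def test_penalty_selection_agrees(self, fed_and_plain):
        fed, plain = fed_and_plain
        assert fed.r_star == plain.r_star
        assert fed.sigma2 == pytest.approx(plain.sigma2, rel=1e-8)


class TestPartitionInvariance:
    def test_node_count_does_not_change_results(self, small_config_module, small_study_module):
        X, Z, y = small_study_module.pooled()
        s = small_study_module
        tables = []
        for P in (1, 2):
            Xs, Zs, ys, off = partition_across_nodes(X, Z, y, P)
            st = SimulatedStudy(Xs, Zs, ys, s.snps, s.causal_idx, s.beta, s.alpha, off)
            res = run_federated_gwas(st, small_config_module, audit_rows=False)
            tables.append(res.table["chisq"].to_numpy())
        assert np.abs(tables[0] - tables[1]).max() < 1e-8


class TestPrivacyAudit:
    def test_only_catalogued_payload_kinds(self, fed_and_plain):
        fed, _ = fed_and_plain
        assert fed.transcript.kinds() <= msg.CATALOGUE

    def test_no_unpadded_private_dimensions(self, fed_and_plain, small_study_module):
        """No message dimension equals a node's sample count, the covariate
        column count, or a SNP block size."""
        fed, _ = fed_and_plain
        private_dims = {g.shape[0] for g in small_study_module.genotypes}
        private_dims.add(small_study_module.covariates[0].shape[1] + 1)
        private_dims.add(40)  # block size
        for record in fed.transcript.records:
            if record.kind in (msg.MASKED_COUNTS, msg.SUM_COUNTS, msg.PUBLIC_DIMS,
                               msg.ASSOC_TEST, msg.RESULT_CHISQ):
                continue  # SNP-indexed payloads; M is public
            assert not (set(record.shape) & private_dims), (record.kind, record.shape)

    def test_no_raw_data_rows_in_transcript(self, fed_and_plain, small_study_module):
        fed, _ = fed_and_plain
        observed = fed.transcript.all_row_digests()
        for p in range(small_study_module.n_nodes):
            for source in (
                small_study_module.genotypes[p],
                small_study_module.covariates[p],
                small_study_module.phenotypes[p][:, None],
            ):
                arr = np.asarray(source, dtype=np.float64)
                for row in arr:
                    assert row_digest(row) not in observed
            # whole vectors too
            assert row_digest(small_study_module.phenotypes[p]) not in observed

    def test_message_census_matches_stage_definitions(self, fed_and_plain, small_config_module, small_study_module):
        """The transcript contains exactly the messages the staged protocol
        prescribes for (P, K, B, R) — nothing extra flows through the server."""
        fed, _ = fed_and_plain
        P = small_study_module.n_nodes
        K = small_config_module.grid.n_folds
        R = small_config_module.grid.n_penalties
        m_kept = int(fed.keep_mask.sum())
        B = -(-m_kept // small_config_module.grid.block_size)
        from collections import Counter

        census = Counter(r.kind for r in fed.transcript.records)
        assert census[msg.MASKED_COUNTS] == P
        assert census[msg.SUM_COUNTS] == P
        assert census[msg.PROJ_Z] == census[msg.PROJ_X] == census[msg.PROJ_Y] == P
        assert census[msg.PROJ_X_RESULT] == census[msg.PROJ_Y_RESULT] == P
        assert census[msg.L0_PHENO] == P * K
        assert census[msg.L0_DESIGN] == P * K * B * R
        assert census[msg.L0_GRAM] == P * K * B * R
        assert census[msg.ASSOC_TEST] == P * K
        assert census[msg.RESULT_CHISQ] == P


class TestDegenerateAndOptions:
    def test_snp_shuffle_returns_same_table(self, small_config_module, small_study_module):
        import copy

        cfg = copy.deepcopy(small_config_module)
        cfg.shuffle_snps = True
        res_shuffled = run_federated_gwas(small_study_module, cfg, audit_rows=False)
        cfg.shuffle_snps = False
        res_plain = run_federated_gwas(small_study_module, cfg, audit_rows=False)
        assert np.abs(
            res_shuffled.table["chisq"].to_numpy() - res_plain.table["chisq"].to_numpy()
        ).max() < 1e-10

    def test_missing_data_handled_end_to_end(self):
        cfg = PipelineConfig(
            simulation=SimulationConfig(
                n_samples=200, n_snps=60, n_covariates=1, n_nodes=2,
                n_causal=3, heritability=0.3, missing_rate=0.05, seed=13,
            ),
            grid=GridConfig(n_folds=3, n_penalties=2, block_size=30),
            seed=13,
        )
        study = simulate_study(cfg.simulation)
        assert any((g == MISSING).any() for g in study.genotypes)
        fed = run_federated_gwas(study, cfg, audit_rows=False)
        X, Z, y = study.pooled()
        plain = run_plaintext_gwas(X, Z, y, cfg, snps=study.snps)
        diff = np.abs(fed.table["chisq"].to_numpy() - plain.table["chisq"].to_numpy())
        assert (diff / (1.0 + plain.table["chisq"].to_numpy())).max() < 1e-6
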