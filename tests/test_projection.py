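"""Covariate projection: plaintext oracle and encoded round trips."""

import numpy as np
import pytest

from fedgwas.encoding import SharedSeed
from fedgwas.projection import (
    decode_projection,
    encode_for_projection,
    impute_and_standardize_stats,
    intercept_augment,
    make_projection_encoders,
    project_covariates_plaintext,
    project_out,
    server_projection,
)


class TestPlaintextProjector:
    def test_intercept_only_centers_and_scales(self):
        X = np.array([[1.0], [2.0], [3.0]])
        Z = np.empty((3, 0))
        y = np.array([1.0, 2.0, 4.0])
        X_proj, y_proj, c = project_covariates_plaintext(X, Z, y)
        sd = np.std([1, 2, 3])
        assert np.allclose(X_proj[:, 0], np.array([-1, 0, 1]) / sd)
        assert c == 1

    def test_orthogonal_column_is_fixed_point(self, rng):
        Z = rng.standard_normal((20, 2))
        Z1 = intercept_augment(Z)
        x = rng.standard_normal(20)
        x -= Z1 @ np.linalg.lstsq(Z1, x, rcond=None)[0]  # orthogonalize
        assert np.allclose(project_out(Z1, x[:, None])[:, 0], x, atol=1e-10)

    def test_projector_idempotent(self, rng):
        Z1 = intercept_augment(rng.standard_normal((30, 3)))
        A = rng.standard_normal((30, 5))
        once = project_out(Z1, A)
        assert np.abs(project_out(Z1, once) - once).max() < 1e-10

    def test_rank_deficient_covariates_named(self, rng):
        Z = rng.standard_normal((20, 2))
        Z = np.column_stack([Z, Z[:, 0]])  # duplicate column
        with pytest.raises(ValueError, match="collinear"):
            project_covariates_plaintext(np.ones((20, 1)) + np.arange(20)[:, None], Z, rng.standard_normal(20))

    def test_constant_phenotype_rejected(self, rng):
        with pytest.raises(ValueError, match="constant phenotype"):
            project_covariates_plaintext(
                rng.integers(0, 3, (10, 2)).astype(np.int8), np.empty((10, 0)), np.ones(10)
            )

    def test_mean_imputation_uses_pooled_mean(self):
        X = np.array([[0], [2], [-1], [2]], dtype=np.int8)
        imputed, mean, sd = impute_and_standardize_stats(X)
        assert mean[0] == pytest.approx(4 / 3)
        assert imputed[2, 0] == pytest.approx(4 / 3)


class TestEncodedProjection:
    def _setup(self, rng, N=30, M=12, C=3, P=2):
        sizes = [N // P] * P
        sizes[-1] += N - sum(sizes)
        offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
        X = rng.integers(0, 3, size=(N, M)).astype(np.int8)
        Z = rng.standard_normal((N, C))
        y = rng.standard_normal(N)
        seed = SharedSeed(77)
        enc = make_projection_encoders(seed, N, C + 1, M)
        return X, Z, y, sizes, offsets, enc

    def test_payload_shapes_are_padded(self, rng):
        X, Z, y, sizes, offsets, enc = self._setup(rng)
        p = encode_for_projection(enc, X[: sizes[0]].astype(float), Z[: sizes[0]], y[: sizes[0]], 0)
        # no payload dimension equals the node's sample count or C+1
        for payload in p.values():
            assert sizes[0] not in payload.shape
            assert Z.shape[1] + 1 not in payload.shape

    def test_server_side_sum_equals_pooled_encoding(self, rng):
        X, Z, y, sizes, offsets, enc = self._setup(rng)
        payloads = [
            encode_for_projection(
                enc,
                X[o : o + s].astype(float), Z[o : o + s], y[o : o + s], o,
            )
            for s, o in zip(sizes, offsets)
        ]
        total = sum(p["proj_Z"] for p in payloads)
        Z1 = intercept_augment(Z)
        direct = enc.o_z.matrix @ Z1 @ enc.o_zp.matrix.T
        assert np.abs(total - direct).max() < 1e-10

    def test_distributed_equals_plaintext_oracle(self, rng):
        X, Z, y, sizes, offsets, enc = self._setup(rng)
        imputed, mean, sd = impute_and_standardize_stats(X)
        s_y = float(np.std(y))
        payloads = [
            encode_for_projection(enc, imputed[o : o + s], Z[o : o + s], y[o : o + s], o)
            for s, o in zip(sizes, offsets)
        ]
        out_x, out_y = server_projection(
            [p["proj_Z"] for p in payloads],
            [p["proj_X"] for p in payloads],
            [p["proj_y"] for p in payloads],
            n_cov_cols=Z.shape[1] + 1,
        )
        X_oracle, y_oracle, _ = project_covariates_plaintext(X, Z, y)
        for s, o, rx, ry in zip(sizes, offsets, out_x, out_y):
            X_dec, y_dec = decode_projection(enc, rx, ry, o, s, sd, s_y)
            assert np.abs(X_dec - X_oracle[o : o + s]).max() < 1e-8
            assert np.abs(y_dec - y_oracle[o : o + s]).max() < 1e-8

    def test_decoded_columns_orthogonal_to_covariates(self, rng):
        X, Z, y, sizes, offsets, enc = self._setup(rng, P=1)
        imputed, _, sd = impute_and_standardize_stats(X)
        payload = encode_for_projection(enc, imputed, Z, y, 0)
        out_x, out_y = server_projection(
            [payload["proj_Z"]], [payload["proj_X"]], [payload["proj_y"]]
        )
        X_dec, y_dec = decode_projection(enc, out_x[0], out_y[0], 0, X.shape[0], sd, np.std(y))
        Z1 = intercept_augment(Z)
        assert np.abs(Z1.T @ X_dec).max() < 1e-6 * X.shape[0]
        assert np.abs(Z1.T @ y_dec).max() < 1e-6 * X.shape[0]

    def test_collinear_pooled_covariates_abort(self, rng):
        X, Z, y, sizes, offsets, _ = self._setup(rng)
        Z[:, 2] = Z[:, 0]  # globally collinear
        enc = make_projection_encoders(SharedSeed(78), X.shape[0], Z.shape[1] + 1, X.shape[1])
        payloads = [
            encode_for_projection(enc, X[o : o + s].astype(float), Z[o : o + s], y[o : o + s], o)
            for s, o in zip(sizes, offsets)
        ]
        with pytest.raises(ValueError, match="collinear"):
            server_projection(
                [p["proj_Z"] for p in payloads],
                [p["proj_X"] for p in payloads],
                [p["proj_y"] for p in payloads],
                n_cov_cols=Z.shape[1] + 1,
            )

    def test_identity_encoding_reduces_to_plaintext(self, rng):
        """Degenerate sanity config: all pads 0, O = I makes the server's
        computation literally the plaintext projection."""
        from fedgwas.encoding import ObfuscationMatrix, PhenotypeDecoy
        from fedgwas.projection import ProjectionEncoders

        N, M, C = 12, 4, 2
        X = rng.integers(0, 3, size=(N, M)).astype(float)
        Z = rng.standard_normal((N, C))
        y = rng.standard_normal(N)
        ident = lambda d: ObfuscationMatrix(np.eye(d))
        enc = ProjectionEncoders(
            o_z=ident(N), o_zp=ident(C + 1), o_x=ident(M), o_y=ident(1),
            decoy=PhenotypeDecoy(decoys=np.empty((N, 0)), perm=np.array([0]), k_y=1.0),
        )
        p = encode_for_projection(enc, X, Z, y, 0)
        assert np.abs(p["proj_X"] - X).max() < 1e-12
        out_x, out_y = server_projection([p["proj_Z"]], [p["proj_X"]], [p["proj_y"]])
        Z1 = intercept_augment(Z)
        assert np.abs(out_x[0] - project_out(Z1, X)).max() < 1e-8
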