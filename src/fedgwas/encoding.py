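"""Randomized-encoding primitives.

All nodes hold a shared secret seed unknown to the server.  Every random
object the protocol needs — obfuscation matrices, additive masks, decoy
columns, permutations, fold assignments — is derived deterministically from
(seed, label path), so all nodes reconstruct identical objects without
communication while the server can reconstruct none of them.

Obfuscation matrices are (d+k) x d with exactly orthonormal columns (QR of a
seeded Gaussian): a strict instance of the in-expectation orthonormality the
encoding scheme requires, chosen so that decoding is exact rather than
in-expectation.  The pad count k hides the true dimension d from anyone who
only sees payload shapes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

# closed vocabulary of derivation-path stage labels
STAGE_LABELS = frozenset(
    {
        "qc_counts",
        "moments",
        "folds",
        "proj_oz",
        "proj_ozp",
        "proj_ox",
        "proj_oy",
        "proj_decoy",
        "proj_perm",
        "proj_pads",
        "level0_ox",
        "level0_oy",
        "level0_sign",
        "level0_pads",
        "assoc_shuffle",
        "node",
        "fold",
        "block",
        "penalty",
        "column",
    }
)


@dataclass(frozen=True)
class SharedSeed:
    """The node-side shared secret; never placed in any message."""

    value: int

    def child(self, *path) -> np.random.Generator:
        return np.random.default_rng(self.derive_int(*path))

    def derive_int(self, *path) -> int:
        """Hash (seed, path) to a 64-bit stream seed."""
        h = hashlib.sha256()
        h.update(str(int(self.value)).encode())
        for label in path:
            if isinstance(label, str):
                if label not in STAGE_LABELS:
                    raise ValueError(f"unknown derivation label {label!r}")
                h.update(b"/" + label.encode())
            else:
                h.update(b"#" + str(int(label)).encode())
        return int.from_bytes(h.digest()[:8], "little")


def derive_randomness(seed: SharedSeed, path) -> np.random.Generator:
    """Deterministic stream for a (seed, path) pair."""
    return seed.child(*path)


@dataclass(frozen=True)
class ObfuscationMatrix:
    """(d+k) x d matrix O with O^T O = I_d."""

    matrix: np.ndarray

    @property
    def d(self) -> int:
        return self.matrix.shape[1]

    @property
    def padded(self) -> int:
        return self.matrix.shape[0]

    def encode_left(self, a: np.ndarray) -> np.ndarray:
        """O @ a (rows d -> d+k)."""
        return self.matrix @ a

    def decode_left(self, a: np.ndarray) -> np.ndarray:
        """O^T @ a, the exact inverse of encode_left."""
        return self.matrix.T @ a

    def slice_columns(self, idx: np.ndarray) -> np.ndarray:
        """Column slice O[:, idx]; used by a node owning global rows idx."""
        return self.matrix[:, idx]


def make_obfuscation(d: int, k: int, rng: np.random.Generator) -> ObfuscationMatrix:
    """Seeded (d+k) x d matrix with exactly orthonormal columns."""
    if d < 1:
        raise ValueError("payload dimension d must be >= 1")
    if k < 0:
        raise ValueError("pad count k must be >= 0")
    g = rng.standard_normal((d + k, d))
    q, r = np.linalg.qr(g)
    # fix the QR sign ambiguity so the draw is deterministic across BLAS builds
    q = q * np.sign(np.diag(r))[None, :]
    return ObfuscationMatrix(matrix=np.ascontiguousarray(q))


def draw_pad(rng: np.random.Generator, low: int = 8, high: int = 64) -> int:
    """Seeded pad count; block sizes are hidden because pads are not fixed."""
    return int(rng.integers(low, high + 1))


@lru_cache(maxsize=96)
def _cached_obfuscation(seed_value: int, path: tuple, d: int, k: int) -> ObfuscationMatrix:
    rng = SharedSeed(seed_value).child(*path)
    return make_obfuscation(d, k, rng)


def shared_obfuscation(seed: SharedSeed, path: tuple, d: int, pad: int) -> ObfuscationMatrix:
    """Shared-seed obfuscation matrix; cached so co-resident parties reuse it."""
    return _cached_obfuscation(seed.value, tuple(path), d, pad)


# ---------------------------------------------------------------------------
# addition-based masking


@dataclass
class AdditiveMaskSet:
    """Per-node masks r_i plus their total, all derivable from the shared seed."""

    masks: list[np.ndarray]

    @property
    def total(self) -> np.ndarray:
        return sum(self.masks)


def make_masks(
    seed: SharedSeed, path: tuple, shape: tuple, n_nodes: int, integer: bool = True
) -> AdditiveMaskSet:
    """Masks for one aggregation round.

    Integer masks make the masked sum exact; float masks are bounded so the
    decode cancellation stays at ~1e-10 absolute.
    """
    masks = []
    for p in range(n_nodes):
        rng = seed.child(*path, "node", p)
        if integer:
            masks.append(rng.integers(-(2**40), 2**40, size=shape, dtype=np.int64))
        else:
            masks.append(rng.uniform(-(2.0**20), 2.0**20, size=shape))
    return AdditiveMaskSet(masks=masks)


def masked_sum(values: list[np.ndarray], mask_set: AdditiveMaskSet) -> tuple[list[np.ndarray], np.ndarray]:
    """Simulate one addition-based aggregation round in plain function form.

    Returns (per-node encoded payloads, decoded global sum).  The protocol
    module performs the same algebra through the transport; this form is the
    unit-testable core.
    """
    if len(values) != len(mask_set.masks):
        raise ValueError("one value per mask required")
    shapes = {np.asarray(v).shape for v in values}
    if len(shapes) != 1:
        raise ValueError("all summands must share a shape")
    encoded = [np.asarray(v) + m for v, m in zip(values, mask_set.masks)]
    server_total = sum(encoded)
    return encoded, server_total - mask_set.total


# ---------------------------------------------------------------------------
# phenotype decoys


@dataclass
class PhenotypeDecoy:
    """Decoy columns, a column permutation and a non-zero phenotype scalar.

    The phenotype column is hidden uniformly among 1 + k_my columns; k_y is
    a random sign (+-1) applied to the phenotype payloads so the server never
    sees the phenotype's orientation.  A sign (rather than an arbitrary
    scalar) keeps every downstream ridge solve, which the server runs without
    decoding, exactly norm-preserving.
    """

    decoys: np.ndarray            # [N_rows x k_my]
    perm: np.ndarray              # permutation over 1 + k_my columns
    k_y: float                    # +-1

    @property
    def n_columns(self) -> int:
        return 1 + self.decoys.shape[1]


def make_decoy(seed: SharedSeed, n_rows: int, k_my: int, scale: float = 1.0) -> PhenotypeDecoy:
    rng = seed.child("proj_decoy")
    decoys = rng.normal(0.0, scale, size=(n_rows, k_my))
    perm = seed.child("proj_perm").permutation(1 + k_my)
    k_y = float(seed.child("level0_sign").choice([-1.0, 1.0]))
    return PhenotypeDecoy(decoys=decoys, perm=perm, k_y=k_y)


def pad_and_permute(y: np.ndarray, decoy: PhenotypeDecoy, rows: slice | np.ndarray | None = None) -> np.ndarray:
    """[y | M_y] with columns permuted by rho.

    ``rows`` selects the row slice of the global decoy matrix for a node that
    owns only part of the samples.
    """
    d = decoy.decoys if rows is None else decoy.decoys[rows]
    if d.shape[0] != y.shape[0]:
        raise ValueError("decoy rows must match phenotype length")
    stacked = np.column_stack([y, d])
    return stacked[:, decoy.perm]


def unpermute(padded: np.ndarray, decoy: PhenotypeDecoy) -> np.ndarray:
    """Undo rho and return the phenotype column, discarding decoys."""
    if padded.shape[1] != decoy.n_columns:
        raise ValueError("column count does not match the decoy permutation")
    inv = np.argsort(decoy.perm)
    return padded[:, inv][:, 0]


def fold_assignment(seed: SharedSeed, n_samples: int, n_folds: int) -> np.ndarray:
    """Global fold labels from the shared seed.

    A seeded permutation of 0..N-1 followed by rank mod K: every party
    derives identical labels from the shared seed and its sample offsets, and
    the labels depend only on the pooled study, never on how it is
    partitioned across nodes.
    """
    order = seed.child("folds").permutation(n_samples)
    labels = np.empty(n_samples, dtype=np.int64)
    labels[order] = np.arange(n_samples) % n_folds
    return labels
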