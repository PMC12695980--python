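"""On-disk formats: blockwise zipped array archives, PLINK BED, TSV outputs.

Genotypes are stored blockwise in ``.npz`` archives: one int8 array per
vertical SNP block (``block_000``, ``block_001``, ...) plus SNP metadata
arrays and a one-element format-version array.  Missing dosages use the
sentinel -1.  A study manifest (YAML) ties together the per-node archives,
covariate/phenotype tables and sample offsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import MISSING, SimulatedStudy

FORMAT_VERSION = 1


@dataclass
class GenotypeBlockSet:
    """One node's dosage slice split into vertical blocks, plus metadata."""

    blocks: list[np.ndarray]
    snps: pd.DataFrame          # snp_id, chrom, pos, counted_allele

    @property
    def matrix(self) -> np.ndarray:
        return np.hstack(self.blocks) if len(self.blocks) > 1 else self.blocks[0]

    @property
    def n_snps(self) -> int:
        return int(sum(b.shape[1] for b in self.blocks))


def split_blocks(matrix: np.ndarray, block_size: int) -> list[np.ndarray]:
    m = matrix.shape[1]
    return [matrix[:, s : min(s + block_size, m)] for s in range(0, m, block_size)]


def write_blockwise_archive(blockset: GenotypeBlockSet, path) -> None:
    arrays = {f"block_{i:03d}": np.asarray(b, dtype=np.int8) for i, b in enumerate(blockset.blocks)}
    arrays["n_blocks"] = np.array([len(blockset.blocks)], dtype=np.int64)
    arrays["format_version"] = np.array([FORMAT_VERSION], dtype=np.int64)
    arrays["snp_id"] = blockset.snps["snp_id"].to_numpy(dtype="U32")
    arrays["chrom"] = blockset.snps["chrom"].to_numpy(dtype=np.int64)
    arrays["pos"] = blockset.snps["pos"].to_numpy(dtype=np.int64)
    arrays["counted_allele"] = blockset.snps.get(
        "counted_allele", pd.Series(["A1"] * len(blockset.snps))
    ).to_numpy(dtype="U8")
    np.savez_compressed(path, **arrays)


def read_blockwise_archive(path) -> GenotypeBlockSet:
    with np.load(path, allow_pickle=False) as npz:
        names = set(npz.files)
        for required in ("n_blocks", "snp_id", "chrom", "pos"):
            if required not in names:
                raise ValueError(f"archive {path} is missing array {required!r}")
        n_blocks = int(npz["n_blocks"][0])
        blocks = []
        for i in range(n_blocks):
            key = f"block_{i:03d}"
            if key not in names:
                raise ValueError(f"archive {path} is missing block {key!r}")
            block = npz[key]
            if block.dtype != np.int8:
                raise ValueError(f"block {key!r} has dtype {block.dtype}, expected int8")
            blocks.append(block)
        snps = pd.DataFrame(
            {
                "snp_id": npz["snp_id"].astype(str),
                "chrom": npz["chrom"],
                "pos": npz["pos"],
                "counted_allele": npz["counted_allele"].astype(str)
                if "counted_allele" in names
                else "A1",
            }
        )
    total = sum(b.shape[1] for b in blocks)
    if total != len(snps):
        raise ValueError(f"archive {path}: {total} block columns vs {len(snps)} metadata rows")
    return GenotypeBlockSet(blocks=blocks, snps=snps)


# ---------------------------------------------------------------------------
# PLINK .bed/.bim/.fam (read-only, SNP-major)

_BED_MAGIC = bytes([0x6C, 0x1B])
# 2-bit PLINK codes -> counted (A1) allele dosage; 01 is the missing code
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)


def read_plink_bed(prefix) -> GenotypeBlockSet:
    """Decode a .bed/.bim/.fam triplet into dosages counting the A1 allele."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
    )
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    n_samples, m = len(fam), len(bim)
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise ValueError("not a PLINK .bed file (magic mismatch)")
    if raw[2] != 0x01:
        raise ValueError("sample-major .bed files are not supported")
    bytes_per_snp = (n_samples + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if len(body) != bytes_per_snp * m:
        raise ValueError(
            f".bed size {len(body)} does not match {n_samples} samples x {m} SNPs "
            "(.fam line count vs genotype rows)"
        )
    body = body.reshape(m, bytes_per_snp)
    # unpack 2-bit codes, lowest bits first
    codes = np.stack([(body >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2)
    codes = codes.reshape(m, -1)[:, :n_samples]
    dosage = _BED_DECODE[codes].T  # [N x M]
    snps = pd.DataFrame(
        {
            "snp_id": bim["snp_id"].astype(str),
            "chrom": bim["chrom"],
            "pos": bim["pos"],
            "counted_allele": bim["a1"].astype(str),
        }
    )
    return GenotypeBlockSet(blocks=[dosage], snps=snps)


# ---------------------------------------------------------------------------
# study manifest


def write_study(study: SimulatedStudy, outdir, block_size: int = 1000) -> Path:
    """Write per-node archives, covariate/phenotype TSVs and the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    node_entries = []
    for p in range(study.n_nodes):
        geno_path = outdir / f"node{p}_genotypes.npz"
        blockset = GenotypeBlockSet(
            blocks=split_blocks(study.genotypes[p], block_size), snps=study.snps
        )
        write_blockwise_archive(blockset, geno_path)
        cov_path = outdir / f"node{p}_covariates.tsv"
        pd.DataFrame(
            study.covariates[p],
            columns=[f"cov{j}" for j in range(study.covariates[p].shape[1])],
        ).to_csv(cov_path, sep="\t", index=False)
        phe_path = outdir / f"node{p}_phenotype.tsv"
        pd.DataFrame({"phenotype": study.phenotypes[p]}).to_csv(phe_path, sep="\t", index=False)
        node_entries.append(
            {
                "genotypes": geno_path.name,
                "covariates": cov_path.name,
                "phenotype": phe_path.name,
                "n_samples": int(study.genotypes[p].shape[0]),
                "offset": int(study.offsets[p]),
            }
        )
    from .simulate import truth_table

    truth_table(study).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    manifest = {
        "format_version": FORMAT_VERSION,
        "n_samples": study.n_samples,
        "n_snps": study.n_snps,
        "n_nodes": study.n_nodes,
        "nodes": node_entries,
    }
    path = outdir / "manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path


def read_study(manifest_path) -> SimulatedStudy:
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    base = manifest_path.parent
    genotypes, covariates, phenotypes, offsets = [], [], [], []
    snps = None
    for entry in manifest["nodes"]:
        blockset = read_blockwise_archive(base / entry["genotypes"])
        genotypes.append(blockset.matrix)
        snps = blockset.snps
        covariates.append(pd.read_csv(base / entry["covariates"], sep="\t").to_numpy())
        phenotypes.append(pd.read_csv(base / entry["phenotype"], sep="\t")["phenotype"].to_numpy())
        offsets.append(entry["offset"])
    snps = snps.copy()
    if "ancestral_freq" not in snps:
        snps["ancestral_freq"] = np.nan
    truth_path = base / "truth.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t")
        beta = truth["beta"].to_numpy()
        causal_idx = np.flatnonzero(truth["is_causal"].to_numpy())
    else:
        beta = np.zeros(len(snps))
        causal_idx = np.zeros(0, dtype=int)
    return SimulatedStudy(
        genotypes=genotypes,
        covariates=covariates,
        phenotypes=phenotypes,
        snps=snps,
        causal_idx=causal_idx,
        beta=beta,
        alpha=np.zeros(covariates[0].shape[1]),
        offsets=np.asarray(offsets),
    )


def write_association_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
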