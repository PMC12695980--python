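"""Synthetic quantitative-trait study generator.

Genotypes follow a Balding–Nichols model: each SNP has an ancestral allele
frequency p, and each of ``n_subpops`` subpopulations draws its own frequency
from Beta(p(1-F)/F, (1-p)(1-F)/F) with F = ``fst``, so the between-population
frequency variance is F * p * (1-p).  Dosages are sums of two Bernoulli
haplotypes.  Family relatedness is emulated by letting a configured fraction
of samples come in pairs that share one parental haplotype draw.  The
phenotype is y = Z a + X_s b + e with b supported on a causal set and scaled
so the genetic variance fraction of y equals the configured heritability.

Missing genotypes are encoded with the sentinel ``MISSING`` (-1) in int8
dosage matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig, node_proportions

MISSING = np.int8(-1)

# variance of each covariate's fixed effect when alpha is not supplied
_DEFAULT_ALPHA_SD = 0.5


@dataclass
class SimulatedStudy:
    """A horizontally partitioned study plus its generative truth."""

    genotypes: list[np.ndarray]        # per node, int8 [N_p x M], -1 = missing
    covariates: list[np.ndarray]       # per node, float [N_p x C]
    phenotypes: list[np.ndarray]       # per node, float [N_p]
    snps: pd.DataFrame                 # snp_id, chrom, pos, ancestral_freq
    causal_idx: np.ndarray             # indices of causal SNPs
    beta: np.ndarray                   # length-M true effect vector
    alpha: np.ndarray                  # length-C covariate effects
    offsets: np.ndarray                # per-node global sample offsets

    @property
    def n_nodes(self) -> int:
        return len(self.genotypes)

    @property
    def n_samples(self) -> int:
        return int(sum(g.shape[0] for g in self.genotypes))

    @property
    def n_snps(self) -> int:
        return int(self.genotypes[0].shape[1])

    def pooled(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Row-concatenate the node slices back into the global study."""
        X = np.vstack(self.genotypes)
        Z = np.vstack(self.covariates)
        y = np.concatenate(self.phenotypes)
        return X, Z, y


def _subpop_labels(n_samples: int, n_subpops: int) -> np.ndarray:
    # contiguous, near-even subpopulation blocks
    sizes = np.full(n_subpops, n_samples // n_subpops)
    sizes[: n_samples % n_subpops] += 1
    return np.repeat(np.arange(n_subpops), sizes)


def simulate_genotypes(config: SimulationConfig) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw the global dosage matrix and SNP metadata.

    Returns an int8 [N x M] matrix with entries in {0,1,2} plus the missing
    sentinel, and a metadata frame with one row per SNP.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x47454E]))
    N, M = config.n_samples, config.n_snps
    F = config.fst

    ancestral = rng.uniform(0.05, 0.95, size=M)
    labels = _subpop_labels(N, config.n_subpops)
    if F > 0 and config.n_subpops > 1:
        a = ancestral * (1.0 - F) / F
        b = (1.0 - ancestral) * (1.0 - F) / F
        subpop_freq = rng.beta(a[None, :], b[None, :], size=(config.n_subpops, M))
    else:
        subpop_freq = np.tile(ancestral, (config.n_subpops, 1))
    freq = subpop_freq[labels]  # [N x M] per-sample allele frequency

    # haplotype draws; related pairs share hap1
    hap1 = (rng.random((N, M)) < freq).astype(np.int8)
    hap2 = (rng.random((N, M)) < freq).astype(np.int8)
    n_pairs = int(config.relatedness * N / 2)
    if n_pairs > 0:
        members = rng.choice(N, size=2 * n_pairs, replace=False)
        first, second = members[:n_pairs], members[n_pairs:]
        hap1[second] = hap1[first]
    dosage = hap1 + hap2

    if config.missing_rate > 0:
        miss = rng.random((N, M)) < config.missing_rate
        dosage[miss] = MISSING

    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{j}" for j in range(M)],
            "chrom": np.ones(M, dtype=int),
            "pos": np.arange(1, M + 1),
            "ancestral_freq": ancestral,
        }
    )
    return dosage, snps


def simulate_phenotype(
    genotypes: np.ndarray,
    config: SimulationConfig,
    alpha: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw covariates and the phenotype on the global study.

    Genotypes are standardized internally (missing treated as the SNP mean)
    before effects are applied.  Returns (Z, y, causal_idx, beta, alpha).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x504845]))
    N, M = genotypes.shape
    C = config.n_covariates

    Z = rng.standard_normal((N, C)) if C else np.empty((N, 0))
    if alpha is None:
        alpha = rng.normal(0.0, _DEFAULT_ALPHA_SD, size=C) if C else np.empty(0)
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (C,):
        raise ValueError("alpha must have one entry per covariate")

    G = genotypes.astype(float)
    G[genotypes == MISSING] = np.nan
    mean = np.nanmean(G, axis=0)
    sd = np.nanstd(G, axis=0)
    sd[sd == 0] = 1.0
    Gs = (np.where(np.isnan(G), mean, G) - mean) / sd

    beta = np.zeros(M)
    causal_idx = np.sort(rng.choice(M, size=config.n_causal, replace=False))
    h2 = config.heritability
    e = rng.standard_normal(N)
    cov_part = Z @ alpha

    if config.n_causal and h2 > 0:
        beta[causal_idx] = rng.standard_normal(config.n_causal)
        g0 = Gs @ beta
        vg0 = float(np.var(g0))
        if h2 == 1.0:
            # pure-genetic phenotype: no noise, no covariate effects
            y = g0 / np.sqrt(vg0) if vg0 > 0 else g0
            return Z, y, causal_idx, beta / np.sqrt(vg0) if vg0 > 0 else beta, np.zeros(C)
        v_env = float(np.var(e)) + float(np.var(cov_part))
        scale = np.sqrt(h2 * v_env / ((1.0 - h2) * vg0)) if vg0 > 0 else 0.0
        beta *= scale
    y = Gs @ beta + cov_part + e
    return Z, y, causal_idx, beta, alpha


def partition_across_nodes(
    genotypes: np.ndarray,
    covariates: np.ndarray,
    phenotypes: np.ndarray,
    n_nodes: int,
    proportions=None,
) -> tuple[list[np.ndarray], list[np.ndarray], list[np.ndarray], np.ndarray]:
    """Split the global study into contiguous per-node row slices.

    Each node's global sample offset (samples added to the study before it)
    is returned alongside the slices.
    """
    props = node_proportions(n_nodes, proportions)
    N = genotypes.shape[0]
    sizes = np.floor(np.asarray(props) * N).astype(int)
    sizes[: N - sizes.sum()] += 1  # distribute the remainder
    if (sizes < 1).any():
        raise ValueError(f"a node was assigned 0 samples (sizes {sizes.tolist()})")
    offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    Xs, Zs, ys = [], [], []
    for off, size in zip(offsets, sizes):
        Xs.append(genotypes[off : off + size])
        Zs.append(covariates[off : off + size])
        ys.append(phenotypes[off : off + size])
    return Xs, Zs, ys, offsets


def simulate_study(
    config: SimulationConfig,
    proportions=None,
    alpha: np.ndarray | None = None,
) -> SimulatedStudy:
    """Generate and partition a full synthetic study."""
    dosage, snps = simulate_genotypes(config)
    Z, y, causal_idx, beta, alpha_out = simulate_phenotype(dosage, config, alpha=alpha)
    Xs, Zs, ys, offsets = partition_across_nodes(dosage, Z, y, config.n_nodes, proportions)
    return SimulatedStudy(
        genotypes=Xs,
        covariates=Zs,
        phenotypes=ys,
        snps=snps,
        causal_idx=causal_idx,
        beta=beta,
        alpha=alpha_out,
        offsets=offsets,
    )


def truth_table(study: SimulatedStudy) -> pd.DataFrame:
    """Truth record: snp_id, is_causal, beta."""
    is_causal = np.zeros(study.n_snps, dtype=bool)
    is_causal[study.causal_idx] = True
    return pd.DataFrame(
        {"snp_id": study.snps["snp_id"], "is_causal": is_causal, "beta": study.beta}
    )
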