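"""SNP-level quality control from pooled genotype counts.

Only the four per-SNP genotype counts (hom-ref, het, hom-alt, missing) are
needed, so in the distributed setting QC runs entirely on masked count sums.
Filters: missing rate (denominator: all pooled samples), minor allele
frequency and the 1-df Hardy–Weinberg goodness-of-fit statistic (denominators:
called genotypes only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import QcThresholds
from .simulate import MISSING


@dataclass
class SnpCounts:
    """Per-SNP genotype counts; arrays of equal length M."""

    hom_ref: np.ndarray
    het: np.ndarray
    hom_alt: np.ndarray
    missing: np.ndarray

    @property
    def n_snps(self) -> int:
        return len(self.hom_ref)

    @property
    def n_samples(self) -> np.ndarray:
        return self.hom_ref + self.het + self.hom_alt + self.missing

    @property
    def n_called(self) -> np.ndarray:
        return self.hom_ref + self.het + self.hom_alt

    def as_matrix(self) -> np.ndarray:
        """[M x 4] int64 matrix (the payload shape used for masked sums)."""
        return np.stack([self.hom_ref, self.het, self.hom_alt, self.missing], axis=1)

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "SnpCounts":
        return cls(hom_ref=m[:, 0], het=m[:, 1], hom_alt=m[:, 2], missing=m[:, 3])


def local_counts(genotypes: np.ndarray) -> SnpCounts:
    """Exact tabulation of one node's dosage matrix (columns = SNPs)."""
    g = np.asarray(genotypes)
    valid = (g == 0) | (g == 1) | (g == 2) | (g == MISSING)
    if not valid.all():
        bad = np.unique(g[~valid])
        raise ValueError(f"dosages outside {{0,1,2,missing}}: {bad.tolist()}")
    return SnpCounts(
        hom_ref=(g == 0).sum(axis=0).astype(np.int64),
        het=(g == 1).sum(axis=0).astype(np.int64),
        hom_alt=(g == 2).sum(axis=0).astype(np.int64),
        missing=(g == MISSING).sum(axis=0).astype(np.int64),
    )


def aggregate_counts(per_node: list[SnpCounts]) -> SnpCounts:
    """Pool per-node counts (plaintext path; the protocol masks the sums)."""
    sizes = {c.n_snps for c in per_node}
    if len(sizes) != 1:
        raise ValueError(f"SNP count mismatch across nodes: {sorted(sizes)}")
    total = sum(c.as_matrix() for c in per_node)
    return SnpCounts.from_matrix(total)


def alt_allele_freq(counts: SnpCounts) -> np.ndarray:
    """Pooled alternate-allele frequency p_hat over called genotypes."""
    called = counts.n_called
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2.0 * counts.hom_alt + counts.het) / (2.0 * called)
    return np.where(called > 0, p, np.nan)


def hwe_chisq(counts: SnpCounts) -> np.ndarray:
    """1-df Hardy–Weinberg goodness-of-fit statistic per SNP.

    Expected genotype counts come from the pooled allele frequency; missing
    genotypes are excluded.  Monomorphic SNPs (an expected count of zero) get
    a statistic of 0 — they are removed by the MAF filter anyway.
    """
    n = counts.n_called.astype(float)
    if (n < 1).any():
        raise ValueError("HWE requires at least one called genotype per SNP")
    p = alt_allele_freq(counts)
    q = 1.0 - p
    exp = np.stack([n * q * q, 2.0 * n * p * q, n * p * p], axis=1)
    obs = np.stack([counts.hom_ref, counts.het, counts.hom_alt], axis=1).astype(float)
    mono = (p == 0.0) | (p == 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.nansum(np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0), axis=1)
    return np.where(mono, 0.0, stat)


def apply_filters(
    counts: SnpCounts,
    thresholds: QcThresholds | None = None,
    snp_ids=None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """QC report and keep-mask from pooled counts.

    keep <=> missing_rate <= max_missing ("exceeding" fails) AND
             maf > min_maf (strictly greater passes) AND
             hwe_chisq <= max_hwe.
    """
    thresholds = thresholds or QcThresholds()
    thresholds.validate()
    if counts.n_snps == 0:
        raise ValueError("empty pooled study")
    n_total = counts.n_samples.astype(float)
    if (n_total < 1).any():
        raise ValueError("empty pooled study")
    missing_rate = counts.missing / n_total
    p = alt_allele_freq(counts)
    maf = np.minimum(p, 1.0 - p)
    hwe = hwe_chisq(counts)
    pass_missing = missing_rate <= thresholds.max_missing_rate
    pass_maf = maf > thresholds.min_maf
    pass_hwe = hwe <= thresholds.max_hwe_chisq
    keep = pass_missing & pass_maf & pass_hwe
    monomorphic = (p == 0.0) | (p == 1.0)
    report = pd.DataFrame(
        {
            "snp_id": snp_ids if snp_ids is not None else [f"snp{j}" for j in range(counts.n_snps)],
            "missing_rate": missing_rate,
            "maf": maf,
            "hwe_chisq": hwe,
            "pass_missing": pass_missing,
            "pass_maf": pass_maf,
            "pass_hwe": pass_hwe,
            "monomorphic": monomorphic,
            "pass": keep,
        }
    )
    return report, keep


def standardization_from_counts(counts: SnpCounts) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP mean and population SD, exactly recoverable from counts.

    mean = 2 p_hat; E[g^2] = (het + 4 hom_alt) / called; SD^2 = E[g^2] - mean^2.
    Residual missing dosages are mean-imputed before standardization, so the
    moments over called genotypes are the ones used throughout.
    """
    called = counts.n_called.astype(float)
    if (called < 1).any():
        raise ValueError("no called genotypes for some SNP")
    mean = 2.0 * alt_allele_freq(counts)
    second = (counts.het + 4.0 * counts.hom_alt) / called
    var = second - mean**2
    if (var <= 0).any():
        raise ValueError("zero-variance SNP reached standardization; run QC first")
    return mean, np.sqrt(var)


def write_report(report: pd.DataFrame, path) -> None:
    out = report.copy()
    reasons = []
    for _, row in out.iterrows():
        failed = [
            name
            for name, ok in (
                ("missing", row["pass_missing"]),
                ("maf", row["pass_maf"]),
                ("hwe", row["pass_hwe"]),
            )
            if not ok
        ]
        reasons.append(",".join(failed) if failed else ".")
    out["reason"] = reasons
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
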