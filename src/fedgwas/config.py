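"""Configuration containers for simulation, QC and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml


@dataclass
class SimulationConfig:
    """Parameters of the synthetic quantitative-trait study.

    The generator produces dosage genotypes (0/1/2, optionally missing) with
    Balding–Nichols population structure controlled by ``fst``, a fraction of
    sample pairs sharing a parental haplotype (``relatedness``), Gaussian
    covariates, and a phenotype y = Z a + X b + e whose genetic variance
    fraction is ``heritability``.
    """

    n_samples: int = 2000
    n_snps: int = 5000
    n_covariates: int = 3
    n_nodes: int = 2
    n_subpops: int = 2
    fst: float = 0.1
    relatedness: float = 0.25
    n_causal: int = 50
    heritability: float = 0.5
    missing_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_snps < 1:
            raise ValueError("n_samples and n_snps must be positive")
        if self.n_covariates < 0:
            raise ValueError("n_covariates must be non-negative")
        if self.n_nodes < 1 or self.n_samples < self.n_nodes:
            raise ValueError("need n_nodes >= 1 and at least one sample per node")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be positive")
        if not (0.0 <= self.fst < 1.0):
            raise ValueError(f"fst must lie in [0, 1), got {self.fst}")
        if not (0.0 <= self.relatedness < 1.0):
            raise ValueError(f"relatedness must lie in [0, 1), got {self.relatedness}")
        if not (0 <= self.n_causal <= self.n_snps):
            raise ValueError("n_causal must lie in [0, n_snps]")
        if not (0.0 <= self.heritability <= 1.0):
            raise ValueError("heritability must lie in [0, 1]")
        if self.heritability == 1.0 and self.n_causal == 0:
            raise ValueError("heritability 1 requires at least one causal SNP")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass
class QcThresholds:
    """SNP-level quality-control thresholds.

    A SNP is retained iff missing_rate <= max_missing_rate, MAF > min_maf and
    the 1-df Hardy–Weinberg goodness-of-fit statistic <= max_hwe_chisq.  The
    default HWE cut-off is the 1-df chi-square inverse survival value at
    p = 1e-6.
    """

    max_missing_rate: float = 0.1
    min_maf: float = 0.05
    max_hwe_chisq: float = 23.928

    def validate(self) -> None:
        if not (0.0 <= self.max_missing_rate <= 1.0):
            raise ValueError("max_missing_rate must lie in [0, 1]")
        if not (0.0 <= self.min_maf < 0.5):
            raise ValueError("min_maf must lie in [0, 0.5)")
        if self.max_hwe_chisq < 0:
            raise ValueError("max_hwe_chisq must be non-negative")


@dataclass
class GridConfig:
    """Stacked-ridge controls: folds K, penalties R, vertical block size."""

    n_folds: int = 5
    n_penalties: int = 5
    block_size: int = 1000

    def validate(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_penalties < 2:
            raise ValueError("n_penalties must be >= 2")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")


@dataclass
class SolverConfig:
    """Iterative-solver controls for the distributed stages.

    admm_penalty is the consensus penalty (learning rate); ``None`` selects a
    scale-aware default per ridge parameter.  Residual balancing keeps the
    primal/dual residuals within a factor of 10 of each other.
    """

    admm_max_iter: int = 500
    admm_tol: float = 1e-10
    admm_penalty: float | None = None
    admm_over_relax: float = 1.7
    cg_max_iter: int = 200
    cg_tol: float = 1e-13

    def validate(self) -> None:
        if self.admm_max_iter < 1 or self.cg_max_iter < 1:
            raise ValueError("iteration caps must be positive")
        if not (1.0 <= self.admm_over_relax < 2.0):
            raise ValueError("over-relaxation must lie in [1, 2)")


@dataclass
class PipelineConfig:
    """Flat top-level configuration for a full run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QcThresholds = field(default_factory=QcThresholds)
    grid: GridConfig = field(default_factory=GridConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    significance_p: float = 5e-8
    shuffle_snps: bool = False
    seed: int = 0

    def validate(self) -> None:
        self.simulation.validate()
        self.qc.validate()
        self.grid.validate()
        self.solver.validate()
        if not (0.0 < self.significance_p < 1.0):
            raise ValueError("significance_p must lie in (0, 1)")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = cls(
            simulation=SimulationConfig(**raw.get("simulation", {})),
            qc=QcThresholds(**raw.get("qc", {})),
            grid=GridConfig(**raw.get("grid", {})),
            solver=SolverConfig(**raw.get("solver", {})),
            significance_p=raw.get("significance_p", 5e-8),
            shuffle_snps=raw.get("shuffle_snps", False),
            seed=raw.get("seed", 0),
        )
        return cfg


def node_proportions(n_nodes: int, proportions: Sequence[float] | None) -> list[float]:
    """Normalize a node-share vector, defaulting to an even split."""
    if proportions is None:
        return [1.0 / n_nodes] * n_nodes
    if len(proportions) != n_nodes:
        raise ValueError("proportions length must equal n_nodes")
    total = float(sum(proportions))
    if abs(total - 1.0) > 1e-8:
        raise ValueError("proportions must sum to 1")
    return [float(p) for p in proportions]
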