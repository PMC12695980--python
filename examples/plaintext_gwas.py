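"""Centralized stacked-ridge GWAS on pooled data.

Fits the two-level ridge model (per-block Level-0 predictors combined by a
cross-validated Level-1 ridge) and tests every SNP against the polygenic-
adjusted residual with a 1-df chi-square.  With 20 causal SNPs at
heritability 0.5, the top hits should be causal and the genomic inflation
under the polygenic model should stay near 1.
"""

import numpy as np
from scipy import stats

from fedgwas import PipelineConfig, SimulationConfig, run_plaintext_gwas, simulate_study
from fedgwas.config import GridConfig

config = PipelineConfig(
    simulation=SimulationConfig(
        n_samples=1500, n_snps=2000, n_covariates=2, n_nodes=1,
        n_causal=20, heritability=0.5, seed=7,
    ),
    grid=GridConfig(n_folds=5, n_penalties=5, block_size=500),
    seed=7,
)
study = simulate_study(config.simulation)
X, Z, y = study.pooled()
result = run_plaintext_gwas(X, Z, y, config, snps=study.snps)

table = result.table
causal_ids = set(study.snps["snp_id"].iloc[study.causal_idx])
top10 = table.sort_values("chisq", ascending=False).head(10)
print(f"{len(table)} SNPs tested; selected penalty index r* = {result.r_star}")
print(f"residual variance sigma^2 = {result.sigma2:.3f}")
print("\ntop 10 SNPs (is_causal marks the simulation's truth):")
for _, row in top10.iterrows():
    print(f"  {row['snp_id']:>8}  chi2={row['chisq']:8.2f}  p={row['p']:.2e}  causal={row['snp_id'] in causal_ids}")

lam_gc = np.median(table["chisq"]) / stats.chi2.ppf(0.5, 1)
print(f"\nmedian chi2 ratio (genomic-control lambda): {lam_gc:.3f}")
print("below 1 is expected here: every tested SNP is also inside the fold-excluded")
print("whole-genome predictor, which absorbs part of each marginal signal; the")
print("type-I error at nominal alpha stays calibrated (see the acceptance tests)")
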