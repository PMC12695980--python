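# Methods

## The model

`fedgwas` performs genome-wide association testing for a quantitative trait
under the standard polygenic model

    y = beta_test * x_test + Z alpha + X beta + e,

where `y` is the phenotype of N individuals, `x_test` the standardized
alternate-allele dosage of the variant under test, `Z` an N x C matrix of
covariates, `X beta` the polygenic background over M standardized variants,
and `e` Gaussian noise.  Instead of maximizing the mixed-model likelihood
(which requires the kinship matrix), the polygenic background is estimated by
a two-level stacked ridge regression in the REGENIE lineage:

* **Level 0.** The projected genotype matrix is split into B contiguous
  vertical blocks.  For each block b and each ridge penalty
  `lambda_r = M (1 - h_r^2) / h_r^2`, with `h_r` linear on [0.01, 0.99] over
  R grid points, a ridge estimator is fitted on the samples outside fold k
  and used to predict fold k.  The out-of-fold predictions form an
  N x (B*R) feature matrix W.
* **Level 1.** A second ridge regression of the phenotype on W, with
  penalties `omega_r = (B R / M) lambda_r`, is fitted per fold; the penalty
  index r* minimizing the summed out-of-fold residual sum of squares is
  selected (ties break toward the strongest penalty), and the whole-genome
  predictor y_hat is assembled from the per-fold out-of-fold predictions.

Each SNP is then scored against the polygenic-adjusted residual:

    chi2 = (x~^T (y~ - y_hat))^2 / (sigma^2 * x~^T x~),
    sigma^2 = ||y~ - y_hat||^2 / (N - C1),

a 1-df statistic, where `x~`, `y~` are the covariate-projected, standardized
test vector and phenotype and C1 counts the columns of the
intercept-augmented covariate matrix Z1 = [Z | 1] (the exact rank removed by
the projection).  Two-sided p-values come from the 1-df chi-square survival
function; the conventional genome-wide threshold p < 5e-8 is exposed as
configuration.

Covariate projection and standardization happen in one computation:

    X~ = (I - Z1 (Z1^T Z1)^{-1} Z1^T) X S_X,

with S_X the diagonal of reciprocal per-SNP standard deviations.  Appending
the all-ones column makes the projector mean-center every column, so no
separate centering pass is needed.  Standardization moments are population
(divide-by-n) moments computed exactly from pooled genotype counts: mean
2*p_hat and variance (n_het + 4 n_homalt)/n_called - mean^2, over called
genotypes.  Residual missing dosages (after the QC missingness filter) are
mean-imputed per SNP before projection, the standard fallback when upstream
imputation is unavailable.

"LOCO" fold exclusion here means K-fold exclusion of the sample's own fold,
not leave-one-chromosome-out; the simulated genome is a single chromosome
and chromosome-aware hold-out is out of scope.  A consequence worth knowing:
each tested SNP is also part of the whole-genome predictor, so a share of
its marginal signal is absorbed and the median test statistic is deflated
below 1 in polygenic simulations.  Under the global null the test stays
calibrated (checked by the acceptance suite); for strong sparse signals the
causal SNP still dominates the ranking.

## Quality control

SNP filters run on pooled per-SNP genotype counts only: missing rate
(denominator: all pooled samples) at most 0.1 — "exceeding" fails; minor
allele frequency strictly greater than 0.05 (denominator: called genotypes);
1-df Hardy–Weinberg goodness-of-fit statistic at most 23.928, the 1-df
chi-square inverse survival value at p = 1e-6.  Monomorphic SNPs get an HWE
statistic of 0 with a flag (the MAF filter removes them anyway).  The HWE
test is the plain goodness-of-fit statistic, not an exact test: a chi-square
threshold paired with a chi-square p-value implies the former.

## The distributed protocol

The study is horizontally partitioned across P computational nodes; a
central server coordinates but must learn nothing about raw genotypes,
covariates, phenotypes, or true per-node dimensions.  All node-side
randomness derives from a shared secret seed (assumed established out of
band; hierarchical SHA-256 label-hashing maps (seed, stage, fold, block,
penalty, node) to child streams), so all nodes construct identical random
objects without communication while the server can construct none of them.

Two randomized-encoding primitives carry every stage:

* **Additive masking** for count-type aggregation: node i sends x_i + r_i;
  the server returns the sum; nodes subtract the (seed-derived) mask total.
  Integer masks are 64-bit uniform draws, so count sums are exact.  Real
  masks (phenotype moments) are uniform on ±2^20, leaving decode
  cancellation error near 1e-10 absolute.
* **Orthonormal-column obfuscation**: a (d+k) x d matrix O with O^T O = I_d
  (QR of a seeded Gaussian, sign-fixed for determinism), k a seeded pad in
  {8..64} that hides the true dimension.  Exact column-orthonormality is a
  strict instance of the in-expectation condition the encoding needs; it is
  chosen so every decode is exact rather than in-expectation, which is what
  makes the distributed results match the centralized ones to solver
  precision.  The sample-indexed matrices (O_Z for projection, O_y per fold
  at Level 0) are single global matrices of which each node uses the column
  slice for its sample range, known from its onboarding offset; this is the
  only reading under which the server-side sums of per-node payloads are
  algebraically consistent.

**Projection stage.**  Each node sends O_Z Z1_p O_Z'^T, O_Z X_p O_X^T and
O_Z [y_p | M_y] rho O_y^T, where M_y are decoy columns and rho a secret
column permutation hiding which column is the phenotype.  With
T = sum_p O_Z Z1_p O_Z'^T, the server returns payload_p − (O_Z Z1_p O_Z'^T)
T^+ sum_q payload_q to node p, which decodes its projected slice exactly and
applies the S_X (and 1/s_y) scaling as the final step.  T^+ is the
Moore–Penrose pseudo-inverse: padding makes T rank-deficient by
construction, so a plain inverse of T^T T does not exist; the pseudo-inverse
reproduces the plaintext projector exactly.  A pooled covariate rank below
C+1 aborts the protocol with a collinearity diagnostic.

**Level 0 (consensus ADMM).**  For each (fold k, block b, penalty r) the
global ridge problem over row-partitioned data is solved by consensus ADMM
entirely on the server, in the encoded coordinate system.  Nodes send, once
per combination:

* the conjugated inverted regularized Gram
  O_X (X~_(p,train)^T X~_(p,train) + ell_r I)^{-1} O_X^T,
* the encoded design operator s * O_y[:, slice_p] X~_(p,k) O_X^T
  (s a seed-derived secret sign), and
* the encoded fold phenotype O_y[:, slice_p] y~_(p,k).

The server forms per-node cross-products by summing transposed
design-phenotype products over the training folds and iterates the exact
Gauss–Seidel consensus updates (per-node primal via the inverted Gram,
over-relaxed averaging, consensus shrinkage by lambda_r, dual ascent).
Because all payloads are conjugations by orthonormal-column matrices, the
encoded iteration is the plaintext iteration in an unknown basis, and the
converged consensus equals the closed-form ridge solution.  The ADMM penalty
is `ell_r = sqrt(lambda_r (lambda_r + n_train/P))` — the geometric mean of
the ridge penalty and the per-node data scale (standardized columns have
squared norm of order the row count) — computed from public quantities so
nodes and server agree without communication; across the whole penalty grid
this converges in under ~100 iterations on representative shapes.  Stopping
is on relative primal and dual residuals (default 1e-10) with stall
detection: the iteration's floating-point noise floor sits near
eps * ||dual|| / ||primal||, and once progress stalls there the best iterate
is accepted if below 1e-7 relative, otherwise the protocol aborts.  This
floor, not the tolerance, bounds the final distributed-vs-centralized
discrepancy at roughly 1e-7 absolute on chi-square values.

Design choices forced by exactness: the block basis O_X is indexed by
(block, penalty) and shared across folds, because the server must sum
cross-fold products in one basis; the fold basis O_y is indexed by fold
only, because the Level-1 Gram mixes columns across penalties and is only
the true Gram when all of a fold's columns share one basis.  Likewise the
phenotype-side scalar is a secret sign in {-1, +1} rather than an arbitrary
non-zero constant: the Level-1 ridge runs blind on the server, and any
non-unit scalar would re-weight the effective Level-1 penalty and break
exact equivalence with the centralized fit — ridge regression is invariant
only under norm-preserving encodings.

**Level 1 (conjugate gradient).**  The server assembles, per fold, the
encoded feature matrix from the Level-0 outputs, forms the BR x BR Gram and
right-hand side over the training folds, and solves
(W^T W + omega_r I) eta = W^T y~ by standard conjugate gradient (tolerance
1e-13, cap min(2*BR, 10*BR) iterations; exact in at most BR steps in exact
arithmetic).  Penalty selection by summed out-of-fold encoded RSS is valid
because left-obfuscations preserve norms.

**Association.**  Nodes send encoded per-fold test-vector blocks
O_y[:, slice_p] X~_(p,k) (all SNPs at once).  The server computes the
chi-square numerator from per-fold inner products with the encoded
residual, the denominator from per-node column norms (exact because column
slices of an orthonormal-column matrix are themselves orthonormal), and
sigma^2 from the encoded residual norm with denominator N − C1.  It returns
the chi-square vector to all nodes; both server and nodes compute p-values.
Optionally the nodes apply a seeded SNP-index shuffle before this stage so
the server cannot link statistics to SNP positions; off by default.

**Fold assignment** is a seeded permutation of the global sample indices
followed by rank mod K.  It depends only on the pooled study and the shared
seed — never on the partition — which is what makes results invariant to
the number of nodes and lets the centralized oracle reproduce the identical
cross-validation split.  Each node checks it has samples in every fold
(guaranteed w.h.p. for node sizes well above K) and aborts otherwise.

**What the server sees.**  The transcript records every message (direction,
stage, kind, shape, optionally a digest of every payload row).  The closed
payload catalogue is: masked count/moment sums, the three projection
payloads, the Level-0 Gram/design/phenotype payloads, encoded association
vectors, the study-level dimension header (N, M after QC, C, B — quantities
the protocol treats as public), and the encoded returns.  The audit asserts
that only catalogued kinds occur, that no message dimension equals a true
per-node sample count, covariate width or block size, and that no row of any
node's raw data appears in any payload.  These are mechanical stand-ins for
the protocol's privacy claims; no cryptographic-strength guarantees are
made (the seeded generators are not cryptographic PRGs, key agreement is
assumed, and the adversary is semi-honest and non-colluding).

## Transport

Two interchangeable backends behind one blocking send/receive interface:
in-process queues with one thread per party (deterministic because each
channel is FIFO and each party's computation is seed-determined), and TCP
sockets with length-prefixed framing (8-byte magic+version, JSON header,
row-major little-endian IEEE-754 body, truncated-SHA1 checksum).  Doubles
round-trip bit-exactly, so the two backends produce bit-identical results.
No TLS: point-to-point links and semi-honest parties are assumed.

## Synthetic data

The generator emulates a quantitative-trait cohort with the structure the
pipeline is designed to absorb:

* **Population structure** via a Balding–Nichols model: ancestral allele
  frequencies uniform on (0.05, 0.95); each of `n_subpops` (default 2)
  subpopulations draws its frequency from
  Beta(p(1-F)/F, (1-p)(1-F)/F) with F = 0.1 by default, giving
  between-population frequency variance F p (1-p).  Dosages are sums of two
  Bernoulli haplotypes.  Subpopulations are contiguous sample blocks, so
  partitioning across nodes correlates ancestry with site, as in real
  consortia.
* **Family relatedness**: a configured fraction (default 0.25) of samples
  form pairs sharing one parental haplotype draw — a stand-in generative
  mechanism chosen because published descriptions of such simulators name
  the relatedness level without defining the mechanism.
* **Missingness**: dosages masked completely at random at rate 0.02 by
  default so the QC filters are exercised.
* **Phenotype**: y = Z alpha + X_s beta + e with beta ~ N(0,1) on a random
  causal set (default 50 SNPs) rescaled so Var(X_s beta)/Var(y) equals the
  target heritability (default 0.5), covariates standard normal with
  effects alpha ~ N(0, 0.5^2) by default, and e standard normal.
  Heritability 1 is the noise-free, covariate-free edge case; heritability 1
  with no causal SNPs is rejected.

What the generator does **not** emulate: linkage disequilibrium beyond what
structure and relatedness induce, realistic allele-frequency spectra, site
batch effects, informative missingness, or binary traits.  Passing tests
therefore certify the algebra and the statistical calibration of the
pipeline under its own model assumptions, not robustness to every artefact
of real cohort data.

## Problem sizes and numerical choices

The acceptance-scale study is N=2000 samples, M=5000 SNPs, C=3 covariates,
P=3 nodes, K=5 folds, R=5 penalties, block size 500 — the scale at which
the full distributed run plus the centralized oracle completes comfortably
on one CPU core (a few minutes) while exercising every stage with non-square
blocks and uneven node slices.  Component tests use instances between N=30
and N=400.  Tolerances: obfuscation orthonormality 1e-10; projection
round-trip vs plaintext 1e-8; distributed vs centralized chi-square
|diff|/(1+chi2) ≤ 1e-6 (mixed absolute/relative, because the ADMM noise
floor is absolute while near-zero statistics make pure relative error
ill-conditioned); node-count invariance 1e-8 absolute; solver-vs-oracle
1e-6 relative.  Rank decisions (covariate collinearity, pseudo-inverse
cutoff) use a relative singular-value threshold of 1e-10.  QR sign fixing
makes obfuscation draws reproducible across BLAS builds.

## Known limitations

* No chromosome-aware LOCO; single-chromosome simulations only.
* Binary traits (logistic/saddlepoint tests) are out of scope.
* Sample-level QC, LD pruning and cross-site variant harmonization are not
  implemented; the QC report is SNP-level only.
* The privacy audit is mechanical, not a security proof; collusion between
  the server and a node, malicious deviations from the protocol, and
  information-theoretic leakage bounds are outside the model.
* Real masked sums carry ~1e-10 absolute decode error; integer sums are
  exact.
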