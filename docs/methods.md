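# Methods

## Model

The phenotype of individual *i* is modeled as

    y_i = beta' X_i + gamma' Z_i + u_i + e_i

with covariate effects `beta` (unpenalized, intercept included), SNP effects
`gamma` on minor-allele dosages, a polygenic random effect `u ~ N(0, Omega)`
and iid residuals `e ~ N(0, sigma2_e I)`. Under minimal or no inbreeding the
polygenic covariance decomposes as `Omega = 2 Phi sigma2_a + Delta sigma2_d`,
where `Phi` is the kinship matrix and `Delta` the matrix of probabilities
that a pair shares both alleles identical by descent. Marginally
`y ~ N(X beta + Z gamma, V(theta))` with `V = Omega + sigma2_e I` and
`theta = (sigma2_a, sigma2_d, sigma2_e)`.

Estimation minimizes the penalized criterion

    Q_lambda = log|V| + r' V^{-1} r + lambda * sum_s |gamma_s|,   r = y - X beta - Z gamma.

Only the SNP coefficients are penalized: the scientific premise is that most
`gamma_s` are zero while covariate effects are nuisance parameters that must
stay unbiased. All likelihood work is maximum likelihood, not REML — the
penalized criterion, the variance-component refits inside it, and the
AIC/BIC comparisons then all live on the same objective. This differs from
common LMM practice; ML variance components are biased low by O(K/n), which
at the default design (n in the hundreds, K = 5) is immaterial next to
sampling noise.

## Relatedness matrices

`Phi` is computed by the standard recursion (phi_ii = (1 + phi_fm)/2,
phi_ij = (phi_fj + phi_mj)/2 recursing on the later individual in a
topological order; founders pairwise unrelated), vectorised row-by-row over
the topological order — O(n^2) and exact. `Delta` uses the non-inbred closed
form `Delta_ij = phi(f_i,f_j) phi(m_i,m_j) + phi(f_i,m_j) phi(m_i,f_j)`.
When a pedigree contains inbreeding the diagonal of Phi still reflects it,
but Delta is knowingly approximate; `Pedigree.inbreeding_audit()` reports
the maximum parental kinship so users can judge the severity. Exact
nine-coefficient identity computation under inbreeding is out of scope.
Parents referenced but not listed in a pedigree file are auto-created as
founders (with a warning) because real PED/FAM files routinely do this.

## Genotype preprocessing

Dosages count copies of the *sample* minor allele (ties at frequency 0.5
keep the ALT-derived coding; the minor allele is recomputed after
subsetting). Two filters run before analysis, in this order:

1. **Minor-allele count**: SNPs with fewer than 10 copies sample-wide are
   dropped — rare variants make penalized coefficient estimates unstable.
2. **Spacing**: a greedy left-to-right scan per chromosome keeps a SNP iff
   it is at least 500 bp (inclusive) past the last kept SNP; the first SNP
   of each chromosome anchors the scan. Greedy keep-first is a documented
   choice — any deterministic rule would do, and this one is order-stable
   and idempotent.

Missing genotypes are imputed per SNP by the mean dosage (or its nearest
integer in {0,1,2}, the default) before filtering.

## Solver

`fit_at_lambda` alternates two blocks until the relative decrease of
Q_lambda falls below 1e-6 (at most 100 outer iterations, else an error
carrying the objective trace):

- **(beta, gamma) block.** V(theta)^{-1/2} whitens (y, X, Z) so the
  quadratic term becomes an ordinary residual sum of squares; the resulting
  LASSO is solved by cyclic coordinate descent with soft thresholding
  (threshold lambda/2, since the quadratic term is not halved), an exact
  least-squares update of beta each sweep, and an active-set refinement
  between full sweeps. Inner tolerance: max coefficient change < 1e-7.
- **theta block.** Variance components are refit by bounded L-BFGS-B on the
  variance scale (sigma2_a, sigma2_d >= 0; sigma2_e floored at
  1e-8 * var(y)), warm-started from the previous theta plus the three-start
  heuristic (equal split of var(r), 90/10 genetic/residual, 10/90) to dodge
  boundary local optima. Optimizing variances directly (rather than
  log-variances with a polish step) lets the genetic components hit exactly
  zero in one pass; the returned optimum is checked against all starts.
  For `Ind` the update is closed form (sigma2_e = r'r/n).

Both blocks decrease Q_lambda, so the objective is non-increasing across
outer iterations; this is asserted at run time (tolerance 1e-7 relative) and
a violation raises. At the returned solution the whitened-LASSO KKT
conditions hold to 1e-4 (normalized by max(1, lambda)).

Genotype columns are centered and scaled to unit standard deviation before
penalization so every SNP feels the same penalty pressure; coefficients are
reported back in dosage units with the centering folded into the intercept.
The solution in original units is invariant to rescaling any dosage column.

For covariance variants with at most one structured component (`Ind`, `Add`)
the likelihood is evaluated through a one-time eigendecomposition of 2 Phi,
making each evaluation O(n) after O(n^3) setup; `AddDom` has two structured
components that cannot be simultaneously diagonalized and uses a dense
Cholesky per evaluation. Both routes are exact and agree to floating-point
precision (tested).

## Lambda path and model selection

`lambda_max = 2 max_s |z*_s' (y* - X* beta_0)|` — evaluated at the
covariates-only variance-component fit on standardized whitened columns —
is the smallest penalty with a guaranteed-empty active set by the KKT
conditions (the factor 2 reflects the unhalved quadratic term). The default
grid is 50 log-spaced points down to 1e-3 * lambda_max, fitted in decreasing
order with warm starts. Each fit records the unpenalized log-likelihood and
`df = |active set| + K + #free variance components` (2 for Add, 3 for
AddDom, 1 for Ind); AIC = -2 loglik + 2 df and BIC = -2 loglik + df log n
select the reported models. Counting only active SNPs in df is available as
a switch via the stored per-fit quantities. Warm-started active-set sizes
can occasionally dip as lambda decreases; the path logs a warning if fewer
than 90% of adjacent grid pairs are non-decreasing.

## Screening

- `ols_scan`: per-SNP OLS of phenotype on dosage plus covariates on a
  mutually unrelated subset (default: pedigree founders), two-sided t test.
  Implemented by Frisch–Waugh projection, vectorised over SNPs; monomorphic
  SNPs get p = 1 and a flag. P-values are floored at 1e-300 so they remain
  in (0, 1].
- `lmm_scan`: the same regression after whitening the full sample by
  V(theta_0) with theta_0 fitted once under the covariates-only null and
  reused for every SNP (per-SNP refits cost n-fold more and change little;
  this is the standard approximate strategy). With Omega = 0 it reduces
  exactly to `ols_scan`.
- `gate`: strict inequality p < threshold.

Covariates are included in each per-SNP regression rather than residualized
out beforehand, avoiding the bias of two-step residualization.

## Synthetic studies

`SimulationConfig` defaults emulate a 20-extended-pedigree design: three
generations with sibships (6, 5) giving 44 members per family (880 total),
founder minor-allele frequencies uniform on (0.05, 0.5), additive polygenic
variance 4 and residual variance 4 on an SBP-like scale (intercept 120; sex,
age, smoking and medication covariates with modest effects), and a small set
of QTLs drawn among SNPs with realized MAF >= 0.1, alternating effect signs.
Genotypes descend from founder alleles by gene dropping — one uniformly
chosen allele per parent per SNP — so the empirical genotype correlation
structure converges to 2 Phi (tested). Positions are laid out on four
synthetic chromosomes with uniform inter-SNP gaps of 200–3000 bp so the
spacing filter and the 2-kbp proximity window are exercisable.

Genotypes and covariates are fixed per (config, seed); phenotype replicates
redraw only u (via Cholesky of Omega with a jitter fallback) and e from the
(seed, replicate) sub-stream. SNPs are simulated in linkage equilibrium:
none of the model's math depends on LD, and LE keeps truth evaluation clean
— but it means passing tests say nothing about LD-induced proxy selection in
real panels, where a selected SNP may tag rather than be the causal variant.
The generator also does not emulate genotyping error, missingness patterns,
population stratification, or ascertainment.

## Evaluation

A selected SNP is a strict hit iff its id is in the truth table, and a
proximal hit iff it lies within 2000 bp (inclusive) of any QTL on the same
chromosome. Reports keep per-replicate rows (selection count, strict hits,
proximal hits) and derive means/SDs and the proportion of replicates with at
least one hit; `compare_methods` tabulates variants side by side with the
percent reduction of mean selection count relative to the largest mean in
the comparison.

## Problem sizes used in the checked results

The test suite and `scripts/acceptance.py` run seeded studies sized for a
single CPU: the confounded-null comparison uses 12 families of 22 (n = 264)
with 120 null SNPs at heritability 0.8 over 30–50 replicates; the power
pipeline 10 families (n = 220) with 150 SNPs and 2 QTLs over 20 replicates;
variance-component recovery the full 880-individual default cohort over
20–50 replicates; the Monte-Carlo IBD oracle uses 10^6 gene drops.

## Known limitations

- Dominance is supported in the covariance, not as per-SNP dominance codes
  in the mean model.
- The `AddDom` likelihood costs O(n^3) per evaluation; n in the low
  thousands is the practical ceiling.
- The unrelated-subset default (founders) is one reasonable reading of
  "unrelated individuals"; founders married into different families are
  unrelated by construction, but a user-supplied subset may match a given
  study better.
- No p-values or confidence intervals accompany selected coefficients; the
  LASSO active set is the deliverable, and post-selection inference is out
  of scope.
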