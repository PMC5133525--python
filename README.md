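# pedlasso

**LASSO-penalized linear mixed models for genome-wide association in samples
of related individuals.**

Family studies (and cohorts with cryptic relatedness) break the assumptions
of standard multi-SNP selection methods: phenotypes of relatives are
correlated through shared polygenic background, and an L1-penalized
regression that treats individuals as independent mistakes that correlation
for marker signal, inflating the number of SNPs it selects. `pedlasso`
implements a penalized mixed model that keeps the LASSO's simultaneous
multi-marker selection while modeling relatedness explicitly, together with
the pedigree machinery, single-marker screens, and simulation tools needed
to run and evaluate a complete two-stage analysis.

## The model

For *n* individuals with quantitative phenotype *y*, covariates *X* (K
columns, intercept included), and minor-allele dosages *Z* (S SNPs, entries
0/1/2):

```
y = X beta + Z gamma + u + e,      u ~ N(0, Omega),   e ~ N(0, sigma2_e I)
Omega = 2 Phi sigma2_a + Delta sigma2_d
```

`Phi` is the pedigree kinship matrix and `Delta` the dominance
(both-alleles-IBD) matrix — both functions of the condensed identity
coefficients, computed here by the standard recursion under the
no-inbreeding approximation. Parameters are estimated by minimizing the
penalized criterion

```
Q_lambda(beta, gamma, theta) = log|V(theta)| + (y - X beta - Z gamma)' V(theta)^{-1} (y - X beta - Z gamma)
                               + lambda * sum_s |gamma_s|,
V(theta) = Omega + sigma2_e I,     theta = (sigma2_a, sigma2_d, sigma2_e),
```

by block coordinate descent: at fixed theta the problem whitens to an
ordinary LASSO solved by cyclic coordinate descent with soft thresholding
(covariates unpenalized); at fixed coefficients theta is refit by bounded
maximum likelihood. Fits are traced over a decreasing lambda grid with warm
starts and the final model is chosen by AIC or BIC. Three covariance
variants are supported: `Add` (additive polygenic), `AddDom` (additive +
dominance), and `Ind` (Omega = 0 — exactly the standard unrelated-samples
LASSO, as a subcase).

Because the penalized model is expensive at GWAS scale, analyses run in two
stages: a single-marker screen (OLS on unrelated founders, or a mixed-model
Wald scan on everyone with null-model variance components) gates SNPs at a
p-value threshold, and the penalized model is fitted on the survivors.

## Worked example

```python
from pedlasso import SimulationConfig, TwoStageConfig, run_two_stage, simulate_study

cfg = SimulationConfig(seed=41, n_families=6, sibship_sizes=(4, 3), n_snps=80,
                       n_qtls=1, qtl_effect_sizes=3.0, sigma2_a=2.0, sigma2_e=2.0)
study = simulate_study(cfg)                      # pedigrees, genotypes, truth
pb = study.phenotypes(0)                         # one phenotype replicate

pipeline = TwoStageConfig(screen_method="lmm", threshold=1e-4,
                          models=("Add",), criterion="bic", n_lambda=25)
res = run_two_stage(pb, study.genotypes, study.ped, pipeline, rel=study.rel)
print(res.selections["Add"]["bic"])
```

prints

```
      id chrom   pos    gamma   lambda
snp00034     2 26390 3.254399 0.040828
```

— one SNP passed the p < 1e-4 mixed-model screen and carries the only
nonzero coefficient in the BIC-optimal penalized fit. It is exactly the
simulated QTL (true effect 3.0 per minor-allele copy; the fitted 3.25
includes sampling noise — shrinkage pulls it toward, not past, zero). The
`examples/` directory has runnable scripts for each capability, including
the headline contrast: under a confounded null (strong polygenic signal,
zero-effect SNPs) the `Add` model selects ~99% fewer false SNPs than the
standard `Ind` LASSO fed the same screened panel.

A thin CLI mirrors the pipeline stages:

```bash
pedlasso simulate --seed 1 --families 8 --snps 300 --out study/
pedlasso kinship study/study.fam --out-prefix study/rel
pedlasso run-all --seed 1 --screen lmm --threshold 1e-4 --model Add --criterion bic --out run/
```

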