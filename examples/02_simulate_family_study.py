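"""Generate a synthetic multi-pedigree association study with known truth.

The generator fixes the pedigrees, gene-dropped genotypes and covariates
once, then redraws the polygenic and residual effects for each phenotype
replicate — so replicate-level discovery summaries are meaningful.
"""

import numpy as np

from pedlasso import SimulationConfig, simulate_study

cfg = SimulationConfig(
    seed=7,
    n_families=8,            # extended 3-generation pedigrees
    n_snps=300,              # markers in linkage equilibrium
    n_qtls=4,                # functional loci with nonzero effects
    qtl_effect_sizes=1.0,    # per-minor-allele-copy, phenotype units
    sigma2_a=4.0,            # additive polygenic variance
    sigma2_e=4.0,            # residual variance
)
study = simulate_study(cfg)

print(f"{len(study.ped)} individuals in {cfg.n_families} families "
      f"({cfg.family_size} members each)")
print(f"{study.genotypes.n_snps} SNPs on {cfg.n_chromosomes} chromosomes")
print("\ntruth table (the QTLs an analysis should recover):")
print(study.truth.to_string(index=False))

y0, y1 = study.phenotypes(0).y, study.phenotypes(1).y
print(f"\nphenotype replicate 0: mean {y0.mean():.2f}, var {y0.var():.2f}")
print(f"phenotype replicate 1: mean {y1.mean():.2f}, var {y1.var():.2f}")
print("replicates share genotypes/covariates but have independent u and e;")
print(f"phenotype correlation between replicates: {np.corrcoef(y0, y1)[0,1]:.3f}")
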