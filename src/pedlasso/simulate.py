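"""Synthetic family-study generator with known truth.

Emulates the structure of a multi-pedigree quantitative-trait study: a fixed
set of extended pedigrees (default 20 three-generation families of 44
members, ~880 individuals), one fixed gene-dropped genotype panel, and
phenotype replicates resimulated from

    y = X beta_true + Z_qtl gamma_true + u + e,
    u ~ N(0, 2*Phi*sigma2_a + Delta*sigma2_d),   e ~ N(0, sigma2_e I).

Genotypes and covariates are identical across replicates; only u and e are
redrawn, so replicate-level discovery summaries (TDR-style proportions) are
meaningful.  SNPs are simulated in linkage equilibrium — founder minor-allele
frequencies drawn per SNP, alleles dropped independently down each pedigree —
which keeps the truth evaluation clean but omits the LD of real panels.

All randomness is seeded; generation is reproducible bit for bit from
(config, seed).  Sub-streams are derived as (seed, tag[, replicate]) so the
pedigree/genotype draw, the covariate draw, the QTL choice and each phenotype
replicate are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, _recode_minor
from .lmm import PhenotypeBlock
from .pedigree import Key, Pedigree, RelatednessMatrices, build_matrices

# sub-stream tags
_T_GENO, _T_COVAR, _T_QTL, _T_PHENO = 1, 2, 3, 4

DEFAULT_COVARIATE_EFFECTS = {
    # SBP-like scale: mm Hg units
    "intercept": 120.0,
    "sex": 4.0,
    "age": 0.3,
    "smoking": 3.0,
    "medication": -5.0,
}


@dataclass
class SimulationConfig:
    """Study-design knobs for the synthetic cohort.

    Defaults emulate a 20-extended-pedigree design: three generations with
    sibships of (6, 5), i.e. 44 members per family and 880 in total; additive
    polygenic variance 4, residual variance 4, no dominance; a handful of
    QTLs among several hundred markers in linkage equilibrium.
    """

    seed: int
    n_families: int = 20
    sibship_sizes: tuple[int, ...] = (6, 5)
    n_snps: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtls: int = 5
    qtl_effect_sizes: float | Sequence[float] = 1.0
    qtl_maf_floor: float = 0.1
    covariate_effects: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    sigma2_a: float = 4.0
    sigma2_d: float = 0.0
    sigma2_e: float = 4.0
    n_replicates: int = 200
    n_chromosomes: int = 4
    spacing_range: tuple[int, int] = (200, 3000)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("simulation requires an explicit seed")
        if min(self.sigma2_a, self.sigma2_d, self.sigma2_e) < 0:
            raise ValueError("variance components must be nonnegative")
        if self.n_qtls > self.n_snps:
            raise ValueError("n_qtls cannot exceed n_snps")
        if not all(s >= 1 for s in self.sibship_sizes):
            raise ValueError("sibship sizes must be positive")

    @property
    def family_size(self) -> int:
        """Members per family implied by the template.

        One founder couple; each generation-k couple has sibship_sizes[k]
        children; every child except those of the last generation marries an
        in-marrying founder spouse.
        """
        total, couples = 2, 1
        for depth, s in enumerate(self.sibship_sizes):
            children = couples * s
            total += children
            if depth < len(self.sibship_sizes) - 1:
                total += children  # spouses
                couples = children
        return total

    @property
    def n_individuals(self) -> int:
        return self.n_families * self.family_size


def simulate_pedigrees(cfg: SimulationConfig) -> Pedigree:
    """Deterministic family template replicated n_families times.

    The structure is fixed by the template; only sexes of within-family
    children are randomized (spouses get the opposite sex), so the same seed
    always yields the identical pedigree.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    members: list[Key] = []
    parents: dict[Key, tuple[Key | None, Key | None]] = {}
    sexes: dict[Key, int] = {}

    for fam_i in range(cfg.n_families):
        fam = f"F{fam_i + 1:02d}"
        counter = [0]

        def new_ind(sex: int, father=None, mother=None) -> Key:
            counter[0] += 1
            key = (fam, f"{fam}_I{counter[0]:03d}")
            members.append(key)
            parents[key] = (father, mother)
            sexes[key] = sex
            return key

        pa = new_ind(1)
        ma = new_ind(2)
        couples = [(pa, ma)]
        for depth, sibship in enumerate(cfg.sibship_sizes):
            last = depth == len(cfg.sibship_sizes) - 1
            next_couples = []
            for f, m in couples:
                for _ in range(sibship):
                    sex = int(rng.integers(1, 3))
                    child = new_ind(sex, father=f, mother=m)
                    if not last:
                        spouse = new_ind(3 - sex)
                        next_couples.append(
                            (child, spouse) if sex == 1 else (spouse, child)
                        )
            couples = next_couples
    return Pedigree(members=members, parents=parents, sex=sexes)


def gene_drop(ped: Pedigree, cfg: SimulationConfig) -> GenotypeMatrix:
    """Drop founder alleles down the pedigree, one draw per SNP.

    Founders receive two independent Bernoulli(maf) allele copies; each
    non-founder inherits one uniformly chosen allele from each parent,
    independently per SNP (linkage equilibrium).  Positions are laid out on
    `n_chromosomes` synthetic chromosomes with inter-SNP gaps drawn uniformly
    from `spacing_range`, so spacing-based filters are exercisable.  Dosages
    are recoded toward the realized sample minor allele.
    """
    rng = np.random.default_rng([cfg.seed, _T_GENO])
    S = cfg.n_snps
    maf = rng.uniform(*cfg.maf_range, size=S)

    topo = ped.topological_order()
    idx = {k: i for i, k in enumerate(topo)}
    n = len(topo)
    alleles = np.zeros((n, 2, S), dtype=np.int8)
    for k in topo:
        i = idx[k]
        f, m = ped.parents[k]
        if f is None:
            alleles[i] = rng.random((2, S)) < maf
        else:
            pick_f = rng.integers(0, 2, size=S)
            pick_m = rng.integers(0, 2, size=S)
            alleles[i, 0] = alleles[idx[f], pick_f, np.arange(S)]
            alleles[i, 1] = alleles[idx[m], pick_m, np.arange(S)]
    dos = alleles.sum(axis=1).astype(float)

    # member-order rows (not topological)
    order = np.array([idx[k] for k in ped.members])
    dos = dos[order]

    per_chrom = int(np.ceil(S / cfg.n_chromosomes))
    chroms, positions = [], []
    for c in range(cfg.n_chromosomes):
        k = min(per_chrom, S - c * per_chrom)
        if k <= 0:
            break
        gaps = rng.integers(cfg.spacing_range[0], cfg.spacing_range[1] + 1, size=k)
        positions.extend(np.cumsum(gaps) + 1000)
        chroms.extend([str(c + 1)] * k)
    snp_map = pd.DataFrame(
        {
            "id": [f"snp{j + 1:05d}" for j in range(S)],
            "chrom": chroms,
            "pos": positions,
            "minor": "A",
            "major": "G",
        }
    )
    g = GenotypeMatrix(dos, snp_map, [k[1] for k in ped.members])
    return _recode_minor(g)


def truth_table(cfg: SimulationConfig, g: GenotypeMatrix) -> pd.DataFrame:
    """Functional-QTL records: id, chrom, pos, gamma_true.

    QTLs are drawn uniformly among SNPs whose realized minor-allele frequency
    is at least `qtl_maf_floor`; effect signs alternate to avoid a net
    directional trend.  Deterministic given (config, seed).
    """
    rng = np.random.default_rng([cfg.seed, _T_QTL])
    maf = g.minor_allele_counts() / (2 * g.n_samples)
    eligible = np.flatnonzero(maf >= cfg.qtl_maf_floor)
    if len(eligible) < cfg.n_qtls:
        raise ValueError(
            f"only {len(eligible)} SNPs above the QTL maf floor; need {cfg.n_qtls}"
        )
    chosen = np.sort(rng.choice(eligible, size=cfg.n_qtls, replace=False))
    effects = np.asarray(
        np.broadcast_to(np.atleast_1d(cfg.qtl_effect_sizes), (cfg.n_qtls,)), dtype=float
    ).copy()
    effects *= np.where(np.arange(cfg.n_qtls) % 2 == 0, 1.0, -1.0)
    rows = g.snp_map.iloc[chosen][["id", "chrom", "pos"]].reset_index(drop=True)
    rows["gamma_true"] = effects
    return rows


def simulate_covariates(ped: Pedigree, cfg: SimulationConfig) -> tuple[np.ndarray, list]:
    """Fixed-across-replicates covariates: intercept, sex, age, smoking, medication."""
    rng = np.random.default_rng([cfg.seed, _T_COVAR])
    n = len(ped)
    sex = np.array([ped.sex.get(k, 0) for k in ped.members], dtype=float)
    sex = np.where(sex == 2, 1.0, 0.0)  # female indicator
    age = rng.normal(50.0, 12.0, size=n).clip(18.0, 90.0)
    smoking = (rng.random(n) < 0.25).astype(float)
    medication = (rng.random(n) < 0.15).astype(float)
    X = np.column_stack([np.ones(n), sex, age, smoking, medication])
    return X, ["intercept", "sex", "age", "smoking", "medication"]


def simulate_phenotypes(
    ped: Pedigree,
    g: GenotypeMatrix,
    rel: RelatednessMatrices,
    cfg: SimulationConfig,
    replicate_index: int,
    truth: pd.DataFrame | None = None,
    _cache: dict | None = None,
) -> PhenotypeBlock:
    """One phenotype replicate of y = X beta + Z_qtl gamma + u + e.

    Covariates, genotypes and the QTL set are fixed by (config, seed); the
    polygenic effect u (covariance 2*Phi*sigma2_a + Delta*sigma2_d, drawn via
    Cholesky with a jitter fallback) and the residual e are redrawn per
    replicate from the (seed, replicate_index) sub-stream.
    """
    cache = _cache if _cache is not None else {}
    if "X" not in cache:
        cache["X"], cache["names"] = simulate_covariates(ped, cfg)
    X, names = cache["X"], cache["names"]
    if truth is None:
        truth = cache.get("truth")
        if truth is None:
            truth = cache["truth"] = truth_table(cfg, g)
    beta = np.array([cfg.covariate_effects.get(nm, 0.0) for nm in names])
    qtl_idx = g.snp_map.set_index("id").index.get_indexer(truth["id"])
    Zq = g.dosages[:, qtl_idx]
    genetic_mean = X @ beta + Zq @ truth["gamma_true"].to_numpy()

    n = len(ped)
    rng = np.random.default_rng([cfg.seed, _T_PHENO, int(replicate_index)])
    u = np.zeros(n)
    if cfg.sigma2_a > 0 or cfg.sigma2_d > 0:
        if "omega_chol" not in cache:
            omega = 2.0 * rel.phi * cfg.sigma2_a + rel.delta * cfg.sigma2_d
            jitter = 0.0
            for _ in range(6):
                try:
                    cache["omega_chol"] = np.linalg.cholesky(omega + jitter * np.eye(n))
                    break
                except np.linalg.LinAlgError:
                    jitter = max(jitter * 10, 1e-10 * np.trace(omega) / n)
            else:
                raise np.linalg.LinAlgError("polygenic covariance not PSD within jitter tolerance")
        u = cache["omega_chol"] @ rng.standard_normal(n)
    e = rng.standard_normal(n) * np.sqrt(cfg.sigma2_e)
    y = genetic_mean + u + e
    return PhenotypeBlock(y=y, X=X, covariate_names=names, sample_order=[k[1] for k in ped.members])


@dataclass
class StudyData:
    """A complete simulated study: structure fixed, phenotypes per replicate."""

    cfg: SimulationConfig
    ped: Pedigree
    genotypes: GenotypeMatrix
    rel: RelatednessMatrices
    truth: pd.DataFrame
    _cache: dict = field(default_factory=dict)

    def phenotypes(self, replicate_index: int) -> PhenotypeBlock:
        return simulate_phenotypes(
            self.ped, self.genotypes, self.rel, self.cfg, replicate_index,
            truth=self.truth, _cache=self._cache,
        )


def simulate_study(cfg: SimulationConfig) -> StudyData:
    """Generate pedigree, genotypes, relatedness and truth for one study."""
    ped = simulate_pedigrees(cfg)
    g = gene_drop(ped, cfg)
    rel = build_matrices(ped)
    truth = truth_table(cfg, g)
    return StudyData(cfg=cfg, ped=ped, genotypes=g, rel=rel, truth=truth)
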