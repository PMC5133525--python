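"""Genotype containers, readers, and preprocessing filters.

Dosages are coded as copies of the sample *minor* allele (0/1/2), with the
minor allele determined from the analysis sample's allele frequency and
recomputed after any subsetting.  Two filters mirror common rare-variant
hygiene for penalized models: a minor-allele-count floor (default 10 copies
over the whole sample) and a physical spacing rule (consecutive retained SNPs
at least 500 bp apart, greedy left-to-right within chromosome).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MAP_COLUMNS = ["id", "chrom", "pos", "minor", "major"]


@dataclass
class GenotypeMatrix:
    """n x S minor-allele dosage matrix with a per-SNP map.

    Attributes
    ----------
    dosages : float array (n, S); entries in {0, 1, 2} or NaN before
        imputation.
    snp_map : DataFrame with columns id, chrom, pos, minor, major, sorted by
        (chrom, pos) with strictly increasing pos within chromosome.
    sample_order : list of sample identifiers defining row order.
    """

    dosages: np.ndarray
    snp_map: pd.DataFrame
    sample_order: list

    def __post_init__(self) -> None:
        self.snp_map = self.snp_map.reset_index(drop=True)
        if self.dosages.shape != (len(self.sample_order), len(self.snp_map)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_order)} samples x {len(self.snp_map)} SNPs"
            )
        grouped = self.snp_map.groupby("chrom", sort=False)["pos"]
        if not grouped.apply(lambda s: s.is_monotonic_increasing and s.is_unique).all():
            raise ValueError("snp_map positions must strictly increase within chromosome")

    @property
    def n_samples(self) -> int:
        return len(self.sample_order)

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)

    def minor_allele_counts(self) -> np.ndarray:
        """Total copies of the minor allele per SNP (missing ignored)."""
        return np.nansum(self.dosages, axis=0)

    def take_snps(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.dosages[:, idx], self.snp_map.iloc[idx], list(self.sample_order)
        )

    def subset_samples(self, sample: Sequence) -> "GenotypeMatrix":
        """Restrict to `sample` and recode toward that subset's minor allele."""
        pos = {s: i for i, s in enumerate(self.sample_order)}
        missing = [s for s in sample if s not in pos]
        if missing:
            raise KeyError(f"samples absent from genotype matrix: {missing}")
        rows = np.array([pos[s] for s in sample])
        g = GenotypeMatrix(self.dosages[rows], self.snp_map.copy(), list(sample))
        return _recode_minor(g)

    def write_tsv(self, genotype_path, map_path) -> None:
        """SNP-major TSV (rows = SNPs, columns = samples) plus sidecar map."""
        ids = [str(s) for s in self.sample_order]
        df = pd.DataFrame(self.dosages.T, index=self.snp_map["id"], columns=ids)
        df.to_csv(genotype_path, sep="\t", index_label="id", na_rep="NA")
        self.snp_map[MAP_COLUMNS].to_csv(map_path, sep="\t", index=False)


def _recode_minor(g: GenotypeMatrix) -> GenotypeMatrix:
    """Flip coding at SNPs where the coded allele has frequency > 0.5.

    Ties at exactly 0.5 keep the current (ALT-derived) coding.
    """
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(g.dosages, axis=0) / 2.0
    flip = freq > 0.5
    if flip.any():
        d = g.dosages.copy()
        d[:, flip] = 2.0 - d[:, flip]
        m = g.snp_map.copy()
        minor = m["minor"].to_numpy().copy()
        major = m["major"].to_numpy().copy()
        minor[flip], major[flip] = major[flip], minor[flip].copy()
        m["minor"], m["major"] = minor, major
        return GenotypeMatrix(d, m, list(g.sample_order))
    return g


def read_genotypes(path, sample_subset: Sequence | None = None, map_path=None) -> GenotypeMatrix:
    """Read genotypes from a VCF or a SNP-major TSV with a sidecar map.

    VCF paths (``.vcf`` / ``.vcf.gz``) are parsed with cyvcf2; biallelic
    sites only (others are skipped with a warning).  Dosages are coded toward
    the sample minor allele.  For the TSV dialect, `map_path` names the
    sidecar file with columns id, chrom, pos, minor, major.
    """
    spath = str(path)
    if spath.endswith((".vcf", ".vcf.gz")):
        g = _read_vcf(spath)
    else:
        if map_path is None:
            raise ValueError("TSV genotype input requires map_path")
        g = _read_tsv(spath, map_path)
    if sample_subset is not None:
        g = g.subset_samples(list(sample_subset))
    return _recode_minor(g)


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    cols, records = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("skipping non-biallelic site %s:%s", var.CHROM, var.POS)
            continue
        gt = var.gt_types.astype(float)  # 0/1/2 ALT copies, 3 = missing
        gt[gt == 3] = np.nan
        cols.append(gt)
        records.append(
            {
                "id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "minor": var.ALT[0],
                "major": var.REF,
            }
        )
    dosages = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return GenotypeMatrix(dosages, pd.DataFrame(records, columns=MAP_COLUMNS), samples)


def _read_tsv(path: str, map_path) -> GenotypeMatrix:
    snp_map = pd.read_csv(map_path, sep="\t", dtype={"chrom": str})
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df = df.loc[snp_map["id"]]
    return GenotypeMatrix(df.to_numpy(dtype=float).T, snp_map, list(df.columns))


def filter_mac(g: GenotypeMatrix, min_count: int = 10) -> GenotypeMatrix:
    """Drop SNPs with fewer than `min_count` minor-allele copies sample-wide.

    With a ~0.01 allele-frequency floor in mind, rare variants give unstable
    coefficient estimates under L1 penalization; the count threshold is
    applied to the whole analysis sample.  Idempotent.
    """
    keep = g.minor_allele_counts() >= min_count
    if not keep.any():
        logger.warning("MAC filter removed every SNP")
    return g.take_snps(keep)


def thin_by_distance(g: GenotypeMatrix, min_gap_bp: int = 500) -> GenotypeMatrix:
    """Greedy per-chromosome spacing filter.

    Scanning left to right, the first SNP of each chromosome is kept and a
    subsequent SNP is kept iff its position is at least `min_gap_bp` past the
    last *kept* position (inclusive: an exact gap of `min_gap_bp` passes).
    Idempotent; preserves SNP order.
    """
    keep = np.zeros(g.n_snps, dtype=bool)
    pos = g.snp_map["pos"].to_numpy()
    chrom = g.snp_map["chrom"].to_numpy()
    last_chrom, last_pos = None, None
    for i in range(g.n_snps):
        if chrom[i] != last_chrom or pos[i] - last_pos >= min_gap_bp:
            keep[i] = True
            last_chrom, last_pos = chrom[i], pos[i]
    return g.take_snps(keep)


def impute_missing(g: GenotypeMatrix, mode: str = "mean_round") -> GenotypeMatrix:
    """Replace missing dosages by the per-SNP mean ('mean') or its nearest
    value in {0,1,2} ('mean_round', default).  SNPs that are entirely missing
    are dropped with a warning."""
    if mode not in ("mean", "mean_round"):
        raise ValueError(f"unknown imputation mode {mode!r}")
    d = g.dosages
    missing = np.isnan(d)
    if not missing.any():
        return g
    all_missing = missing.all(axis=0)
    if all_missing.any():
        logger.warning("dropping %d SNP(s) with no observed genotypes", all_missing.sum())
        g = g.take_snps(~all_missing)
        d = g.dosages
        missing = np.isnan(d)
    col_mean = np.nanmean(d, axis=0)
    if mode == "mean_round":
        col_mean = np.clip(np.round(col_mean), 0, 2)
    d = d.copy()
    d[missing] = np.broadcast_to(col_mean, d.shape)[missing]
    return GenotypeMatrix(d, g.snp_map.copy(), list(g.sample_order))


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write hard-call dosages as a minimal VCF 4.2 (major allele as REF)."""
    d = g.dosages
    if np.isnan(d).any():
        raise ValueError("cannot write missing genotypes; impute first")
    codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        names = "\t".join(str(s) for s in g.sample_order)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{names}\n")
        for j, row in g.snp_map.iterrows():
            gts = "\t".join(codes[int(round(x))] for x in d[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['major']}\t"
                f"{row['minor']}\t.\tPASS\t.\tGT\t{gts}\n"
            )
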