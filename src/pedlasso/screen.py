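"""Phase-I single-marker screening.

Two tests are available, mirroring the common GWAS toolbox: an ordinary
least-squares regression per SNP on a set of mutually unrelated individuals
(the test run on founders when family data are available), and a mixed-model
Wald test on the full related sample with the polygenic covariance fitted
once under the covariates-only null and reused for every SNP.  Both include
the covariates in each per-SNP regression.  A p-value gate (strict
inequality) selects the SNPs that advance to the penalized phase II.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .lmm import PhenotypeBlock, fit_null_model, whiten
from .pedigree import RelatednessMatrices

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300  # underflow floor so p values stay in (0, 1]


@dataclass
class ScreenResult:
    """Per-SNP association statistics from a phase-I scan."""

    table: pd.DataFrame  # columns: id, chrom, pos, beta, se, stat, p
    method: str
    threshold: float | None = None

    def passing(self, threshold: float) -> list:
        """SNP ids with p strictly below `threshold`, in map order."""
        t = self.table
        return list(t.loc[t["p"] < threshold, "id"])

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _marginal_scan(y: np.ndarray, X: np.ndarray, Z: np.ndarray, df_resid: int):
    """Per-column regression of y on [X, z] via Frisch–Waugh projection.

    Projects X out of y and every genotype column, then the coefficient on
    the projected column equals the joint-regression coefficient.  Columns
    that are (numerically) constant after projection are monomorphic in the
    analysis sample: effect 0, p = 1.
    """
    Q, _ = np.linalg.qr(X)
    yh = y - Q @ (Q.T @ y)
    Zh = Z - Q @ (Q.T @ Z)
    zz = np.einsum("ij,ij->j", Zh, Zh)
    zy = Zh.T @ yh
    mono = zz <= 1e-12 * max(1.0, float(np.max(zz, initial=0.0)))
    zz_safe = np.where(mono, 1.0, zz)
    beta = zy / zz_safe
    rss = np.maximum(yh @ yh - zy**2 / zz_safe, 0.0)
    sigma2 = rss / df_resid
    se = np.sqrt(np.maximum(sigma2 / zz_safe, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        # se = 0 with a nonzero effect is a perfect fit: statistic diverges
        tstat = np.where(se > 0, beta / se, np.where(beta != 0, np.inf, 0.0))
    p = 2.0 * stats.t.sf(np.abs(tstat), df_resid)
    p = np.clip(p, P_FLOOR, 1.0)
    beta[mono] = 0.0
    se[mono] = np.nan
    tstat[mono] = 0.0
    p[mono] = 1.0
    if mono.any():
        logger.warning("%d monomorphic SNP(s) in scan; p set to 1", mono.sum())
    return beta, se, tstat, p


def _result(g: GenotypeMatrix, method: str, cols) -> ScreenResult:
    beta, se, tstat, p = cols
    table = pd.DataFrame(
        {
            "id": g.snp_map["id"].to_numpy(),
            "chrom": g.snp_map["chrom"].to_numpy(),
            "pos": g.snp_map["pos"].to_numpy(),
            "beta": beta,
            "se": se,
            "stat": tstat,
            "p": p,
        }
    )
    return ScreenResult(table=table, method=method)


def ols_scan(pb: PhenotypeBlock, g: GenotypeMatrix) -> ScreenResult:
    """OLS association test per SNP with covariates, two-sided t test.

    `pb` and `g` must be aligned to the same (unrelated) sample; relatedness
    is NOT modeled here — running this on a related sample is exactly the
    miscalibrated analysis the mixed-model scan exists to fix.
    """
    if g.n_samples != pb.n:
        raise ValueError("phenotype and genotype sample sizes differ")
    if np.isnan(g.dosages).any():
        raise ValueError("missing genotypes; impute before scanning")
    df_resid = pb.n - pb.n_covariates - 1
    return _result(g, "ols_unrelated", _marginal_scan(pb.y, pb.X, g.dosages, df_resid))


def lmm_scan(
    pb: PhenotypeBlock,
    g: GenotypeMatrix,
    rel: RelatednessMatrices,
    model: str = "Add",
) -> ScreenResult:
    """Mixed-model Wald scan on all (related) individuals.

    Variance components are estimated once under the covariates-only null
    and V(theta0) is then fixed; each SNP effect is the generalized-least-
    squares estimate after whitening, tested two-sided against a t
    reference with n - K - 1 degrees of freedom.  With Omega = 0 this
    reduces exactly to :func:`ols_scan`.
    """
    if g.n_samples != pb.n:
        raise ValueError("phenotype and genotype sample sizes differ")
    if np.isnan(g.dosages).any():
        raise ValueError("missing genotypes; impute before scanning")
    _, vc0 = fit_null_model(pb, rel, model)
    ys, Xs, Zs = whiten(pb, g.dosages, rel, vc0)
    df_resid = pb.n - pb.n_covariates - 1
    res = _result(g, "lmm_all", _marginal_scan(ys, Xs, Zs, df_resid))
    res.null_vc = vc0
    return res


def gate(sr: ScreenResult, threshold: float) -> list:
    """SNP ids passing the phase-I p-value gate (p < threshold, strict)."""
    sr.threshold = threshold
    ids = sr.passing(threshold)
    if not ids:
        logger.warning("no SNPs passed the screen at p < %g", threshold)
    return ids
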