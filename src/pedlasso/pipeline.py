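"""Two-stage orchestration and truth-based evaluation.

Stage I: impute, apply the minor-allele-count and spacing filters, then scan
every SNP with either the unrelated-subset OLS test or the all-sample
mixed-model test, and gate at a p-value threshold.  Stage II: fit the
penalized mixed-model path on the surviving SNPs for each requested
covariance variant and select a model by AIC/BIC; the "significant" SNPs of
a run are the active set of the selected fit.  Evaluation scores selections
against the simulator's truth records: strict hits (a selected SNP *is* a
QTL) and proximal hits (within a base-pair window of one, inclusive,
default 2000 bp), aggregated over replicates into means/SDs and the
proportion of replicates with at least one hit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, filter_mac, impute_missing, thin_by_distance
from .lasso import LassoPath, fit_path
from .lmm import PhenotypeBlock
from .pedigree import Pedigree, RelatednessMatrices, build_matrices
from .screen import ScreenResult, gate, lmm_scan, ols_scan

logger = logging.getLogger(__name__)


@dataclass
class TwoStageConfig:
    """Knobs of the filter -> screen -> gate -> LASSO -> select pipeline."""

    screen_method: str = "lmm"  # 'ols' (unrelated subset) or 'lmm' (all samples)
    threshold: float = 1e-4
    models: tuple[str, ...] = ("Add",)
    criterion: str = "bic"
    mac_min: int = 10
    min_gap_bp: int = 500
    n_lambda: int = 50
    lambda_ratio: float = 1e-3
    impute_mode: str = "mean_round"

    def __post_init__(self) -> None:
        if self.screen_method not in ("ols", "lmm"):
            raise ValueError(f"unknown screen method {self.screen_method!r}")
        if self.criterion.lower() not in ("aic", "bic"):
            raise ValueError(f"unknown criterion {self.criterion!r}")


@dataclass
class TwoStageResult:
    """Everything one pipeline run produces."""

    config: TwoStageConfig
    genotypes: GenotypeMatrix  # post-filter panel
    screen: ScreenResult
    passed: list
    paths: dict  # model -> LassoPath (empty when the gate passed nothing)
    selections: dict  # model -> {criterion -> DataFrame(id, chrom, pos, gamma, lambda)}

    def selected_ids(self, model: str, criterion: str | None = None) -> list:
        crit = (criterion or self.config.criterion).lower()
        return list(self.selections[model][crit]["id"])

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.screen.write_tsv(out / "screen.tsv")
        for model, by_crit in self.selections.items():
            for crit, df in by_crit.items():
                df.to_csv(out / f"selected_{model}_{crit}.tsv", sep="\t", index=False)
        for model, path in self.paths.items():
            if path is None:
                continue
            rows = pd.DataFrame(
                {
                    "lambda": path.lambda_grid,
                    "n_active": [f.active_set.size for f in path.fits],
                    "loglik": [f.loglik for f in path.fits],
                    "df": [f.df for f in path.fits],
                    "aic": path.aic,
                    "bic": path.bic,
                }
            )
            rows.to_csv(out / f"path_{model}.tsv", sep="\t", index=False)


def _selection_frame(g: GenotypeMatrix, path: LassoPath | None, criterion: str, keep_idx) -> pd.DataFrame:
    cols = {"id": [], "chrom": [], "pos": [], "gamma": [], "lambda": []}
    if path is not None and path.fits:
        fit = path.selected(criterion)
        snp_rows = g.snp_map.iloc[keep_idx].reset_index(drop=True)
        for j in fit.active_set:
            cols["id"].append(snp_rows.at[j, "id"])
            cols["chrom"].append(snp_rows.at[j, "chrom"])
            cols["pos"].append(int(snp_rows.at[j, "pos"]))
            cols["gamma"].append(float(fit.gamma[j]))
            cols["lambda"].append(float(fit.lam))
    return pd.DataFrame(cols)


def run_two_stage(
    pb: PhenotypeBlock,
    g: GenotypeMatrix,
    ped: Pedigree,
    cfg: TwoStageConfig,
    rel: RelatednessMatrices | None = None,
    unrelated: list | None = None,
    out_dir=None,
) -> TwoStageResult:
    """Run filter -> screen -> gate -> penalized path -> selection.

    `unrelated` names the subset used by the OLS screen (defaults to
    pedigree founders).  An empty gate output is a valid low-power outcome:
    phase II is skipped and selections are empty.
    """
    if rel is None:
        rel = build_matrices(ped, sample=[ped.resolve(s) for s in pb.sample_order])
    g = impute_missing(g, mode=cfg.impute_mode)
    g = filter_mac(g, min_count=cfg.mac_min)
    g = thin_by_distance(g, min_gap_bp=cfg.min_gap_bp)
    logger.info("post-filter panel: %d SNPs", g.n_snps)

    if cfg.screen_method == "ols":
        subset = unrelated if unrelated is not None else [k[1] for k in ped.founders]
        keep = [s for s in subset if s in set(pb.sample_order)]
        pos = {s: i for i, s in enumerate(pb.sample_order)}
        rows = np.array([pos[s] for s in keep])
        pb_sub = PhenotypeBlock(
            y=pb.y[rows], X=pb.X[rows], covariate_names=list(pb.covariate_names),
            sample_order=keep,
        )
        sr = ols_scan(pb_sub, g.subset_samples(keep))
    else:
        sr = lmm_scan(pb, g, rel, model="Add")
    passed = gate(sr, cfg.threshold)

    paths: dict = {}
    selections: dict = {}
    id_index = pd.Index(g.snp_map["id"])
    keep_idx = id_index.get_indexer(passed)
    criteria = ("aic", "bic")
    for model in cfg.models:
        if len(passed) == 0:
            paths[model] = None
            selections[model] = {c: _selection_frame(g, None, c, keep_idx) for c in criteria}
            continue
        Z = g.dosages[:, keep_idx]
        path = fit_path(
            pb, Z, rel, model, n_points=cfg.n_lambda, ratio=cfg.lambda_ratio
        )
        paths[model] = path
        selections[model] = {c: _selection_frame(g, path, c, keep_idx) for c in criteria}

    result = TwoStageResult(
        config=cfg, genotypes=g, screen=sr, passed=passed, paths=paths, selections=selections
    )
    if out_dir is not None:
        result.write(out_dir)
    return result


# ---------------------------------------------------------------------------
# evaluation against simulation truth


@dataclass
class EvaluationReport:
    """Replicate-level discovery summaries against the QTL truth records.

    `per_replicate` has one row per replicate with columns n_significant,
    n_qtls_discovered, n_within_window; aggregates are recomputable from it.
    tdr_any_qtl / tdr_any_proximal are the proportions of replicates with at
    least one strict / proximal hit.
    """

    per_replicate: pd.DataFrame
    window_bp: int
    label: str = ""

    @property
    def n_replicates(self) -> int:
        return len(self.per_replicate)

    def summary(self) -> dict:
        pr = self.per_replicate
        return {
            "label": self.label,
            "n_replicates": self.n_replicates,
            "mean_significant": float(pr["n_significant"].mean()),
            "sd_significant": float(pr["n_significant"].std(ddof=1)) if len(pr) > 1 else 0.0,
            "mean_qtls_discovered": float(pr["n_qtls_discovered"].mean()),
            "sd_qtls_discovered": float(pr["n_qtls_discovered"].std(ddof=1)) if len(pr) > 1 else 0.0,
            "tdr_any_qtl": float((pr["n_qtls_discovered"] > 0).mean()),
            "mean_within_window": float(pr["n_within_window"].mean()),
            "sd_within_window": float(pr["n_within_window"].std(ddof=1)) if len(pr) > 1 else 0.0,
            "tdr_any_proximal": float((pr["n_within_window"] > 0).mean()),
            "window_bp": self.window_bp,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def evaluate(
    selections: list,
    truth: pd.DataFrame,
    snp_map: pd.DataFrame,
    window_bp: int = 2000,
    label: str = "",
) -> EvaluationReport:
    """Score per-replicate selections against truth QTL records.

    `selections` is a list (one entry per replicate) of DataFrames with
    columns id, chrom, pos (as produced by the pipeline) or plain id lists
    (positions then come from `snp_map`).  A strict hit is a selected id
    present in truth; a proximal hit is a selected SNP within `window_bp`
    (inclusive) of any QTL position on the same chromosome.
    """
    truth_ids = set(truth["id"])
    truth_chroms = set(truth["chrom"].astype(str))
    map_chroms = set(snp_map["chrom"].astype(str))
    if not truth_chroms <= map_chroms:
        raise ValueError(
            f"truth chromosomes {sorted(truth_chroms - map_chroms)} absent from snp map"
        )
    by_chrom = {
        str(c): t["pos"].to_numpy() for c, t in truth.groupby(truth["chrom"].astype(str))
    }
    id_rows = snp_map.set_index("id")

    rows = []
    for sel in selections:
        if isinstance(sel, pd.DataFrame):
            ids = list(sel["id"])
            chroms = sel["chrom"].astype(str).to_numpy()
            pos = sel["pos"].to_numpy()
        else:
            ids = list(sel)
            sub = id_rows.loc[ids]
            chroms = sub["chrom"].astype(str).to_numpy()
            pos = sub["pos"].to_numpy()
        n_sig = len(ids)
        n_qtl = sum(1 for i in ids if i in truth_ids)
        n_prox = 0
        for c, p in zip(chroms, pos):
            qpos = by_chrom.get(c)
            if qpos is not None and np.min(np.abs(qpos - p)) <= window_bp:
                n_prox += 1
        rows.append(
            {"n_significant": n_sig, "n_qtls_discovered": n_qtl, "n_within_window": n_prox}
        )
    per_replicate = pd.DataFrame(rows)
    if ((per_replicate["n_qtls_discovered"] > per_replicate["n_significant"]).any()):
        raise AssertionError("more QTL hits than selections in a replicate")
    return EvaluationReport(per_replicate=per_replicate, window_bp=window_bp, label=label)


def compare_methods(reports: dict) -> pd.DataFrame:
    """Side-by-side summary table over covariance variants / criteria.

    Rows are report labels; columns are the replicate-aggregate metrics plus
    the relative reduction (%) of the mean selection count with respect to
    the largest mean in the table (the unrelated-individuals analysis in the
    standard comparison).  All reports must cover the same replicates.
    """
    sizes = {k: r.n_replicates for k, r in reports.items()}
    if len(set(sizes.values())) > 1:
        raise ValueError(f"replicate sets differ across reports: {sizes}")
    rows = {}
    for key, rep in reports.items():
        s = rep.summary()
        s.pop("label", None)
        rows[key] = s
    df = pd.DataFrame(rows).T
    base = df["mean_significant"].max()
    df["reduction_vs_max_pct"] = np.where(
        base > 0, 100.0 * (base - df["mean_significant"]) / base, 0.0
    )
    return df
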