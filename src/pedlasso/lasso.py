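"""L1-penalized linear mixed model: block coordinate descent over a lambda path.

The criterion minimized is

    Q_lambda(beta, gamma, theta)
        = log|V(theta)| + (y - X beta - Z gamma)' V^{-1}(theta) (y - X beta - Z gamma)
        + lambda * sum_s |gamma_s|

with the penalty on the SNP coefficients gamma only; covariate effects beta
are never penalized.  The solver alternates two blocks:

(a) at fixed theta, whiten by V(theta)^{-1/2} and solve the resulting
    ordinary LASSO by cyclic coordinate descent with soft thresholding
    (exact least-squares update for beta);
(b) at fixed (beta, gamma), re-fit theta by bounded maximum likelihood.

Both blocks decrease Q_lambda, so the objective is non-increasing across
outer iterations; this is asserted at run time.  Setting Omega = 0 (model
'Ind') makes step (b) closed form and reduces the whole procedure to the
standard LASSO — the unrelated-individuals method is an exact subcase.

Genotype columns are centered and scaled to unit variance internally so each
SNP feels the same penalty pressure; reported coefficients are mapped back to
per-minor-allele-copy (dosage) units, with the centering absorbed into the
intercept.  Model selection along the path uses AIC or BIC with
df = |active set| + K + (number of free variance components).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .lmm import (
    N_FREE_VC,
    ConvergenceError,
    PhenotypeBlock,
    VarianceComponents,
    _start_points,
    fit_null_model,
    fit_variance_components,
    get_structure,
    log_likelihood,
)
from .pedigree import RelatednessMatrices

logger = logging.getLogger(__name__)


class MonotonicityError(RuntimeError):
    """The penalized objective increased across an outer iteration."""


@dataclass
class LassoFit:
    """A solution of Q_lambda at one penalty value.

    ``beta`` and ``gamma`` are on the original covariate/dosage scales;
    ``gamma_std`` holds the internally penalized standardized coefficients
    (gamma_std = gamma * snp_scale), so that
    objective = loglik core + lam * sum|gamma_std| is recomputable.
    """

    lam: float
    beta: np.ndarray
    gamma: np.ndarray
    gamma_std: np.ndarray
    snp_scale: np.ndarray
    vc: VarianceComponents
    objective: float
    loglik: float
    df: int
    kkt_residual: float
    n_outer: int
    objective_trace: list = field(default_factory=list)

    @property
    def active_set(self) -> np.ndarray:
        return np.flatnonzero(self.gamma_std != 0.0)


@dataclass
class LassoPath:
    """Fits over a decreasing lambda grid with AIC/BIC-selected optima."""

    fits: list
    lambda_grid: np.ndarray
    model: str
    n: int
    selected_aic: int = -1
    selected_bic: int = -1

    def __post_init__(self) -> None:
        if self.fits:
            self.selected_aic = int(np.argmin(self.aic))
            self.selected_bic = int(np.argmin(self.bic))

    @property
    def aic(self) -> np.ndarray:
        return np.array([-2.0 * f.loglik + 2.0 * f.df for f in self.fits])

    @property
    def bic(self) -> np.ndarray:
        return np.array([-2.0 * f.loglik + f.df * np.log(self.n) for f in self.fits])

    def selected(self, criterion: str) -> LassoFit:
        criterion = criterion.lower()
        if criterion == "aic":
            return self.fits[self.selected_aic]
        if criterion == "bic":
            return self.fits[self.selected_bic]
        raise ValueError(f"unknown criterion {criterion!r}")


class _Workspace:
    """Standardized genotypes + cached covariance structure for one problem."""

    def __init__(self, pb: PhenotypeBlock, Z: np.ndarray, rel, model: str):
        self.pb = pb
        Z = np.asarray(Z, dtype=float)
        if Z.ndim != 2 or Z.shape[0] != pb.n:
            raise ValueError("Z must be n x S")
        self.center = Z.mean(axis=0)
        self.scale = Z.std(axis=0)
        if np.any(self.scale <= 0):
            bad = np.flatnonzero(self.scale <= 0)
            raise ValueError(f"constant genotype column(s) at index {bad.tolist()}")
        self.Zs = (Z - self.center) / self.scale
        self.S = Z.shape[1]
        self.struct = get_structure(rel, model, n=pb.n)
        self.rel = rel
        self.model = model
        # intercept column (constant, nonzero) for center back-substitution
        const = np.all(pb.X == pb.X[0], axis=0) & (pb.X[0] != 0)
        self._intercept = int(np.argmax(const)) if const.any() else None

    def whitened(self, vc: VarianceComponents):
        apply, logdet = self.struct.whitener(vc)
        return apply(self.pb.y), apply(self.pb.X), apply(self.Zs), logdet

    def residual_original(self, beta, gamma_std):
        return self.pb.y - self.pb.X @ beta - self.Zs @ gamma_std

    def back_transform(self, beta, gamma_std):
        """Map (beta, standardized gamma) to original dosage-unit scales."""
        gamma = gamma_std / self.scale
        beta_out = beta.copy()
        if self._intercept is not None:
            beta_out[self._intercept] -= (self.center @ gamma) / self.pb.X[0, self._intercept]
        return beta_out, gamma


def _soft(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


def _inner_lasso(ys, Xs, Zts, lam, beta, gamma, tol=1e-7, max_iter=2000):
    """Cyclic coordinate descent for ||ys - Xs b - Zts g||^2 + lam ||g||_1.

    Exact least-squares update of b each sweep; soft-thresholding updates of g
    in column (map) order, with an active-set strategy: after a full sweep,
    iterate on the nonzero coordinates until stable, then re-check all.
    Converged when the largest coefficient change in a full sweep < tol.
    """
    S = Zts.shape[1]
    colsq = np.einsum("ij,ij->j", Zts, Zts)
    XtX = Xs.T @ Xs
    Xpinv = np.linalg.solve(XtX, Xs.T) if np.linalg.matrix_rank(XtX) == XtX.shape[0] else np.linalg.pinv(Xs)
    gamma = gamma.copy()
    beta = beta.copy()
    r = ys - Xs @ beta - Zts @ gamma
    thr = lam / 2.0

    def sweep(indices):
        delta = 0.0
        nonlocal r
        for j in indices:
            gj = gamma[j]
            rho = Zts[:, j] @ r + colsq[j] * gj
            gnew = _soft(rho, thr) / colsq[j]
            if gnew != gj:
                r -= Zts[:, j] * (gnew - gj)
                d = abs(gnew - gj)
                if d > delta:
                    delta = d
                gamma[j] = gnew
        return delta

    all_idx = range(S)
    for it in range(1, max_iter + 1):
        rb = r + Xs @ beta
        beta_new = Xpinv @ rb
        delta = float(np.max(np.abs(beta_new - beta))) if beta.size else 0.0
        r = rb - Xs @ beta_new
        beta = beta_new
        delta = max(delta, sweep(all_idx))
        if delta < tol:
            break
        # active-set refinement between full sweeps
        active = np.flatnonzero(gamma)
        for _ in range(100):
            if sweep(active) < tol:
                break
    else:
        raise ConvergenceError(f"coordinate descent did not converge in {max_iter} sweeps")
    return beta, gamma, r, it


def kkt_residual(Zts, Xs, r, gamma, lam) -> float:
    """Max KKT violation of the whitened LASSO, normalized by max(1, lambda).

    Stationarity requires 2 Zts' r = lam * sign(gamma_j) on the active set,
    |2 Zts' r| <= lam off it, and Xs' r = 0 for the unpenalized block.
    """
    g = 2.0 * (Zts.T @ r)
    on = gamma != 0.0
    resid = np.where(on, np.abs(g - lam * np.sign(gamma)), np.maximum(0.0, np.abs(g) - lam))
    beta_resid = 2.0 * np.max(np.abs(Xs.T @ r)) if Xs.size else 0.0
    return float(max(resid.max(initial=0.0), beta_resid)) / max(1.0, lam)


def penalized_objective(
    pb: PhenotypeBlock,
    Z: np.ndarray,
    rel: RelatednessMatrices | None,
    vc: VarianceComponents,
    beta: np.ndarray,
    gamma: np.ndarray,
    lam: float,
    penalty_scale: np.ndarray | None = None,
) -> float:
    """Evaluate Q_lambda at arbitrary (beta, gamma, theta).

    The penalty is lam * sum|gamma * penalty_scale| (penalty_scale defaults
    to ones, i.e. the coefficients as given).  The solver itself penalizes
    standardized coefficients; pass penalty_scale = snp standard deviations
    to reproduce its internal objective from original-scale gamma.
    """
    struct = get_structure(rel, vc.model, n=pb.n)
    r = pb.y - pb.X @ np.asarray(beta, float) - np.asarray(Z, float) @ np.asarray(gamma, float)
    core = struct.nll_core(vc, r)
    w = np.ones_like(gamma, dtype=float) if penalty_scale is None else np.asarray(penalty_scale, float)
    return core + lam * float(np.sum(np.abs(np.asarray(gamma, float) * w)))


def fit_at_lambda(
    pb: PhenotypeBlock,
    Z: np.ndarray,
    rel: RelatednessMatrices | None,
    model: str,
    lam: float,
    init: LassoFit | None = None,
    *,
    inner_tol: float = 1e-7,
    outer_tol: float = 1e-6,
    max_outer: int = 100,
    _workspace: _Workspace | None = None,
) -> LassoFit:
    """Block coordinate descent for Q_lambda at a single penalty value.

    Alternates the whitened coordinate-descent LASSO (beta, gamma block)
    with a maximum-likelihood refit of theta until the relative decrease of
    Q_lambda falls below `outer_tol` (or `max_outer` iterations, an error).
    The objective trace is retained on the returned fit and is checked to be
    non-increasing.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    ws = _workspace or _Workspace(pb, Z, rel, model)

    if init is not None:
        beta = init.beta.copy()
        gamma_std = init.gamma_std.copy()
        # undo the intercept centering adjustment: internal beta works with Zs
        if ws._intercept is not None:
            beta[ws._intercept] += (ws.center @ (gamma_std / ws.scale)) / pb.X[0, ws._intercept]
        vc = init.vc
    else:
        # start from the converged covariates-only model, the same point that
        # defines lambda_max, so the empty active set is exact at the boundary
        beta, vc = fit_null_model(pb, rel, model)
        gamma_std = np.zeros(ws.S)

    trace: list[float] = []
    prev_q = np.inf
    n_outer = 0
    for n_outer in range(1, max_outer + 1):
        ys, Xs, Zts, logdet = ws.whitened(vc)
        beta, gamma_std, r_w, _ = _inner_lasso(ys, Xs, Zts, lam, beta, gamma_std, tol=inner_tol)
        q = logdet + float(r_w @ r_w) + lam * float(np.sum(np.abs(gamma_std)))
        trace.append(q)
        if q > prev_q + 1e-7 * (1.0 + abs(prev_q)):
            raise MonotonicityError(
                f"Q_lambda increased from {prev_q} to {q} at outer iteration {n_outer}"
            )
        if prev_q - q < outer_tol * (1.0 + abs(q)):
            prev_q = q
            break
        prev_q = q
        r_orig = ws.residual_original(beta, gamma_std)
        vc = _refit_vc(ws, r_orig, rel, model, vc)
    else:
        raise ConvergenceError(
            f"outer loop did not converge in {max_outer} iterations; trace={trace}"
        )

    # final bookkeeping at the converged (beta, gamma, theta)
    ys, Xs, Zts, logdet = ws.whitened(vc)
    r_w = ys - Xs @ beta - Zts @ gamma_std
    core = logdet + float(r_w @ r_w)
    kkt = kkt_residual(Zts, Xs, r_w, gamma_std, lam)
    beta_out, gamma_out = ws.back_transform(beta, gamma_std)
    active = int(np.count_nonzero(gamma_std))
    df = active + pb.n_covariates + N_FREE_VC[model]
    return LassoFit(
        lam=float(lam),
        beta=beta_out,
        gamma=gamma_out,
        gamma_std=gamma_std,
        snp_scale=ws.scale.copy(),
        vc=vc,
        objective=core + lam * float(np.sum(np.abs(gamma_std))),
        loglik=log_likelihood(core, pb.n),
        df=df,
        kkt_residual=kkt,
        n_outer=n_outer,
        objective_trace=trace,
    )


def _refit_vc(ws: _Workspace, r_orig, rel, model, vc_prev):
    """Theta block update: ML fit on the current residual, warm-started."""
    pb = ws.pb
    if model == "Ind":
        return VarianceComponents(0.0, 0.0, max(float(r_orig @ r_orig) / pb.n, 1e-300), "Ind")
    warm = [np.array([vc_prev.sigma2_a, vc_prev.sigma2_e])] if model == "Add" else [
        np.array([vc_prev.sigma2_a, vc_prev.sigma2_d, vc_prev.sigma2_e])
    ]
    dummy = PhenotypeBlock(
        y=r_orig, X=np.zeros((pb.n, 0)), covariate_names=[], sample_order=list(pb.sample_order)
    )
    vtot = max(float(np.var(r_orig)), 1e-10)
    starts = warm + _start_points(model, vtot)
    return fit_variance_components(dummy, None, np.zeros(0), None, rel, model, starts=starts)


def lambda_grid(
    pb: PhenotypeBlock,
    Z: np.ndarray,
    rel: RelatednessMatrices | None,
    model: str,
    n_points: int = 50,
    ratio: float = 1e-3,
) -> np.ndarray:
    """Log-spaced penalty grid from lambda_max down to ratio * lambda_max.

    lambda_max = 2 * max_s |z*_s' (y* - X* beta0)|, evaluated at the
    covariates-only variance-component fit with standardized whitened
    genotype columns z*_s — by the KKT conditions the smallest penalty at
    which the active set is empty.
    """
    ws = _Workspace(pb, Z, rel, model)
    beta0, vc0 = fit_null_model(pb, rel, model)
    ys, Xs, Zts, _ = ws.whitened(vc0)
    beta_w = np.linalg.lstsq(Xs, ys, rcond=None)[0]
    r0 = ys - Xs @ beta_w
    lam_max = 2.0 * float(np.max(np.abs(Zts.T @ r0)))
    if not np.isfinite(lam_max) or lam_max <= 0:
        raise ValueError("degenerate genotype matrix: cannot determine lambda_max")
    return np.geomspace(lam_max, ratio * lam_max, n_points)


def fit_path(
    pb: PhenotypeBlock,
    Z: np.ndarray,
    rel: RelatednessMatrices | None,
    model: str,
    n_points: int = 50,
    ratio: float = 1e-3,
    grid: np.ndarray | None = None,
    **fit_kwargs,
) -> LassoPath:
    """Warm-started fits over the whole lambda grid with AIC/BIC selection.

    Individual lambda values whose fit fails to converge are skipped with a
    warning provided at least 80% of the grid succeeds; otherwise the error
    propagates.
    """
    if Z.ndim != 2 or Z.shape[1] < 1:
        raise ValueError("need at least one SNP column after screening")
    if grid is None:
        grid = lambda_grid(pb, Z, rel, model, n_points=n_points, ratio=ratio)
    ws = _Workspace(pb, Z, rel, model)
    fits: list[LassoFit] = []
    kept_lams = []
    prev = None
    failures = 0
    for lam in grid:
        try:
            fit = fit_at_lambda(
                pb, Z, rel, model, float(lam), init=prev, _workspace=ws, **fit_kwargs
            )
        except (ConvergenceError, MonotonicityError) as err:
            failures += 1
            logger.warning("fit at lambda=%.4g failed: %s", lam, err)
            if failures > 0.2 * len(grid):
                raise
            continue
        fits.append(fit)
        kept_lams.append(float(lam))
        prev = fit
    sizes = np.array([f.active_set.size for f in fits])
    if len(sizes) > 1:
        nondecr = np.mean(np.diff(sizes) >= 0)
        if nondecr < 0.9:
            logger.warning(
                "active-set size non-monotone along path (%.0f%% non-decreasing)",
                100 * nondecr,
            )
    return LassoPath(fits=fits, lambda_grid=np.array(kept_lams), model=model, n=pb.n)
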