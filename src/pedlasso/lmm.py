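"""Unpenalized linear mixed-model machinery.

The phenotype model is

    y = X beta + Z gamma + u + e,   u ~ N(0, Omega),   e ~ N(0, sigma2_e I),

with Omega = 2*Phi*sigma2_a + Delta*sigma2_d from the pedigree.  Everything
here works with the marginal covariance V(theta) = Omega + sigma2_e I and the
Gaussian log-likelihood core

    log|V(theta)| + r' V(theta)^{-1} r,    r = y - X beta - Z gamma,

(the n*log(2*pi) constant is tracked separately for AIC/BIC).  Estimation is
maximum likelihood, not REML: the penalized objective this package exists for
is a penalized ML criterion, and keeping ML throughout makes the information
criteria and the L1 objective coherent.  This differs from common LMM
practice and slightly biases variance components downward in small samples.

Three covariance variants are supported:

- ``Ind``   : Omega = 0 (all individuals treated as unrelated);
- ``Add``   : Omega = 2*Phi*sigma2_a (additive polygenic variance only);
- ``AddDom``: Omega = 2*Phi*sigma2_a + Delta*sigma2_d.

For Ind and Add the likelihood is evaluated through a one-time
eigendecomposition of 2*Phi, after which each evaluation is O(n); AddDom has
two structured components that cannot be simultaneously diagonalized, so it
goes through a dense Cholesky factorization per evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .pedigree import RelatednessMatrices

MODELS = ("Add", "AddDom", "Ind")

#: free variance parameters per covariance variant (for df accounting)
N_FREE_VC = {"Add": 2, "AddDom": 3, "Ind": 1}


class ConvergenceError(RuntimeError):
    """Variance-component optimization failed at every start."""


@dataclass
class VarianceComponents:
    """theta = (sigma2_a, sigma2_d, sigma2_e) plus the covariance variant.

    All components are in squared phenotype units.  ``model='Add'`` forces
    sigma2_d = 0 and ``model='Ind'`` forces sigma2_a = sigma2_d = 0.
    """

    sigma2_a: float
    sigma2_d: float
    sigma2_e: float
    model: str = "AddDom"

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown covariance model {self.model!r}")
        if self.sigma2_a < 0 or self.sigma2_d < 0 or self.sigma2_e <= 0:
            raise ValueError(
                f"variance components must satisfy sigma2_a, sigma2_d >= 0 and "
                f"sigma2_e > 0; got ({self.sigma2_a}, {self.sigma2_d}, {self.sigma2_e})"
            )
        if self.model == "Add" and self.sigma2_d != 0:
            raise ValueError("model 'Add' requires sigma2_d = 0")
        if self.model == "Ind" and (self.sigma2_a != 0 or self.sigma2_d != 0):
            raise ValueError("model 'Ind' requires sigma2_a = sigma2_d = 0")

    @property
    def theta(self) -> tuple[float, float, float]:
        return (self.sigma2_a, self.sigma2_d, self.sigma2_e)

    @property
    def n_free(self) -> int:
        return N_FREE_VC[self.model]


@dataclass
class PhenotypeBlock:
    """Phenotype vector plus fixed-effect covariates (intercept included)."""

    y: np.ndarray
    X: np.ndarray
    covariate_names: list[str]
    sample_order: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("y and X disagree on sample size")
        if np.isnan(self.y).any() or np.isnan(self.X).any():
            raise ValueError("missing values in phenotype or covariates")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("covariate matrix X is rank deficient")
        if len(self.covariate_names) != self.X.shape[1]:
            raise ValueError("covariate_names length must match X columns")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]


def read_phenotypes(path, sample_subset: Sequence | None = None) -> PhenotypeBlock:
    """Read a phenotype/covariate TSV (columns: id, phenotype, covariates...).

    An intercept column is prepended automatically.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if sample_subset is not None:
        df = df.set_index("id").loc[[str(s) for s in sample_subset]].reset_index()
    names = list(df.columns[2:])
    X = np.column_stack([np.ones(len(df)), df[names].to_numpy(dtype=float)])
    return PhenotypeBlock(
        y=df.iloc[:, 1].to_numpy(dtype=float),
        X=X,
        covariate_names=["intercept"] + names,
        sample_order=list(df["id"]),
    )


class CovarianceStructure:
    """Evaluator for V(theta) = 2*Phi*s2a + Delta*s2d + s2e*I at fixed Phi, Delta.

    Precomputes what the chosen variant allows (the eigendecomposition of
    2*Phi for Ind/Add) so that repeated likelihood evaluations during
    optimization are cheap.  Obtain instances via :func:`get_structure`,
    which caches per (relatedness, model) pair.
    """

    def __init__(self, rel: RelatednessMatrices | None, model: str, n: int | None = None):
        if model not in MODELS:
            raise ValueError(f"unknown covariance model {model!r}")
        self.model = model
        self.rel = rel
        self.n = rel.n if rel is not None else int(n)
        if model == "AddDom":
            if rel is None:
                raise ValueError("AddDom requires relatedness matrices")
            self.A = 2.0 * rel.phi
            self.D = rel.delta
        elif model == "Add":
            if rel is None:
                raise ValueError("Add requires relatedness matrices")
            A = 2.0 * rel.phi
            w, U = np.linalg.eigh(A)
            self.eigvals = np.clip(w, 0.0, None)
            self.U = U
        # Ind needs nothing

    # -- covariance assembly ----------------------------------------------

    def covariance(self, vc: VarianceComponents) -> np.ndarray:
        """Dense V(theta); linear in each variance component."""
        self._check(vc)
        n = self.n
        V = vc.sigma2_e * np.eye(n)
        if self.model == "AddDom":
            V += vc.sigma2_a * self.A + vc.sigma2_d * self.D
        elif self.model == "Add":
            V += vc.sigma2_a * (self.U * self.eigvals) @ self.U.T
        return V

    def _check(self, vc: VarianceComponents) -> None:
        if vc.model != self.model:
            raise ValueError(
                f"variance components are for model {vc.model!r}, structure is {self.model!r}"
            )

    # -- whitening ---------------------------------------------------------

    def whitener(self, vc: VarianceComponents):
        """Return (apply, logdet): `apply(M)` maps M to W M with W'W = V^{-1}.

        For Ind/Add, W is diag(d^{-1/2}) U' in the eigenbasis of 2*Phi (an
        orthogonal rotation composed with a rescaling); for AddDom it is
        L^{-1} from the Cholesky factorization V = L L'.  Either way
        ||W r||^2 = r' V^{-1} r exactly.
        """
        self._check(vc)
        if self.model == "Ind":
            s = vc.sigma2_e
            logdet = self.n * np.log(s)
            scale = 1.0 / np.sqrt(s)
            return (lambda M: scale * np.asarray(M, dtype=float)), logdet
        if self.model == "Add":
            d = vc.sigma2_a * self.eigvals + vc.sigma2_e
            if np.any(d <= 0):
                raise np.linalg.LinAlgError(
                    f"V(theta) not positive definite at theta={vc.theta}"
                )
            logdet = float(np.sum(np.log(d)))
            isd = 1.0 / np.sqrt(d)
            U = self.U

            def apply(M):
                M = np.asarray(M, dtype=float)
                out = U.T @ M
                return out * (isd[:, None] if out.ndim == 2 else isd)

            return apply, logdet
        V = self.covariance(vc)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"V(theta) not positive definite at theta={vc.theta}"
            ) from err
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))

        def apply(M, L=L):
            return linalg.solve_triangular(L, np.asarray(M, dtype=float), lower=True)

        return apply, logdet

    def nll_core(self, vc: VarianceComponents, r: np.ndarray) -> float:
        """log|V(theta)| + r' V^{-1}(theta) r."""
        apply, logdet = self.whitener(vc)
        wr = apply(r)
        return logdet + float(wr @ wr)


def get_structure(rel: RelatednessMatrices | None, model: str, n: int | None = None) -> CovarianceStructure:
    """Cached CovarianceStructure per (relatedness instance, model)."""
    if rel is None:
        return CovarianceStructure(None, model, n=n)
    cache = rel.__dict__.setdefault("_structure_cache", {})
    if model not in cache:
        cache[model] = CovarianceStructure(rel, model)
    return cache[model]


def build_covariance(rel: RelatednessMatrices, vc: VarianceComponents) -> np.ndarray:
    """V = 2*Phi*sigma2_a + Delta*sigma2_d + sigma2_e*I as a dense matrix."""
    return get_structure(rel, vc.model, n=rel.n if rel is not None else None).covariance(vc)


def _residual(pb: PhenotypeBlock, beta, gamma, Z) -> np.ndarray:
    r = pb.y - pb.X @ np.asarray(beta, dtype=float)
    if Z is not None and gamma is not None and np.size(gamma):
        r = r - np.asarray(Z, dtype=float) @ np.asarray(gamma, dtype=float)
    return r


def neg_log_likelihood(
    pb: PhenotypeBlock,
    beta: np.ndarray,
    gamma: np.ndarray | None,
    Z: np.ndarray | None,
    rel: RelatednessMatrices | None,
    vc: VarianceComponents,
) -> float:
    """Gaussian likelihood core log|V| + r'V^{-1}r at fixed coefficients.

    Excludes the n*log(2*pi) constant; add it back via :func:`log_likelihood`
    when absolute likelihood values are needed.
    """
    struct = get_structure(rel, vc.model, n=pb.n)
    return struct.nll_core(vc, _residual(pb, beta, gamma, Z))


def log_likelihood(core: float, n: int) -> float:
    """Full Gaussian log-likelihood from the core value."""
    return -0.5 * (core + n * np.log(2.0 * np.pi))


def whiten(
    pb: PhenotypeBlock,
    Z: np.ndarray | None,
    rel: RelatednessMatrices | None,
    vc: VarianceComponents,
):
    """Transform (y, X, Z) so the model has identity error covariance.

    Returns (y*, X*, Z*) with Z* = None when Z is None.  After the transform
    ||y* - X*b - Z*g||^2 equals (y-Xb-Zg)' V^{-1} (y-Xb-Zg) for any (b, g).
    """
    struct = get_structure(rel, vc.model, n=pb.n)
    apply, _ = struct.whitener(vc)
    ys = apply(pb.y)
    Xs = apply(pb.X)
    Zs = apply(Z) if Z is not None else None
    return ys, Xs, Zs


# ---------------------------------------------------------------------------
# variance-component fitting


def _start_points(model: str, vtot: float) -> list[np.ndarray]:
    # 3-start heuristic: equal split, genetic-heavy, residual-heavy
    if model == "Add":
        return [
            np.array([0.5 * vtot, 0.5 * vtot]),
            np.array([0.9 * vtot, 0.1 * vtot]),
            np.array([0.1 * vtot, 0.9 * vtot]),
        ]
    return [
        np.array([vtot / 3, vtot / 3, vtot / 3]),
        np.array([0.45 * vtot, 0.45 * vtot, 0.1 * vtot]),
        np.array([0.05 * vtot, 0.05 * vtot, 0.9 * vtot]),
    ]


def fit_variance_components(
    pb: PhenotypeBlock,
    Z: np.ndarray | None,
    beta: np.ndarray,
    gamma: np.ndarray | None,
    rel: RelatednessMatrices | None,
    model: str,
    starts: Sequence[np.ndarray] | None = None,
) -> VarianceComponents:
    """Maximum-likelihood theta at fixed fixed-effect coefficients.

    Minimizes log|V(theta)| + r'V^{-1}(theta)r over the admissible cone
    (sigma2_a, sigma2_d >= 0; sigma2_e floored at 1e-8 * var(y)) with bounded
    L-BFGS-B from three starts — an equal split of var(r), a 90/10
    genetic/residual split and a 10/90 split — and returns the best local
    optimum.  For model 'Ind' the MLE is closed form: sigma2_e = r'r / n.
    """
    if model not in MODELS:
        raise ValueError(f"unknown covariance model {model!r}")
    r = _residual(pb, beta, gamma, Z)
    n = pb.n
    if model == "Ind":
        return VarianceComponents(0.0, 0.0, max(float(r @ r) / n, 1e-300), "Ind")

    struct = get_structure(rel, model)
    floor_e = 1e-8 * max(float(np.var(pb.y)), 1e-12)
    vtot = max(float(np.var(r)), 10 * floor_e)

    def to_vc(x) -> VarianceComponents:
        if model == "Add":
            return VarianceComponents(max(x[0], 0.0), 0.0, max(x[1], floor_e), "Add")
        return VarianceComponents(
            max(x[0], 0.0), max(x[1], 0.0), max(x[2], floor_e), "AddDom"
        )

    def objective(x) -> float:
        try:
            return struct.nll_core(to_vc(x), r)
        except np.linalg.LinAlgError:
            return np.inf

    if model == "Add":
        bounds = [(0.0, None), (floor_e, None)]
    else:
        bounds = [(0.0, None), (0.0, None), (floor_e, None)]

    start_list = list(starts) if starts is not None else _start_points(model, vtot)
    best, trace = None, []
    for x0 in start_list:
        res = optimize.minimize(
            objective,
            np.asarray(x0, dtype=float),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 200, "ftol": 1e-10},
        )
        trace.append((list(np.asarray(x0)), float(res.fun), bool(res.success)))
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError(f"variance-component optimization failed; trace: {trace}")
    # the returned optimum can be no worse than any start
    start_vals = [objective(x0) for x0 in start_list]
    if best.fun > min(start_vals) + 1e-6 * (1 + abs(min(start_vals))):
        raise ConvergenceError(
            f"optimizer returned objective {best.fun} above best start {min(start_vals)}"
        )
    return to_vc(best.x)


def gls_coefficients(
    pb: PhenotypeBlock,
    rel: RelatednessMatrices | None,
    vc: VarianceComponents,
) -> np.ndarray:
    """Generalized-least-squares covariate coefficients at fixed theta."""
    ys, Xs, _ = whiten(pb, None, rel, vc)
    beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    return beta


def fit_null_model(
    pb: PhenotypeBlock,
    rel: RelatednessMatrices | None,
    model: str,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[np.ndarray, VarianceComponents]:
    """Covariates-only fit: alternate GLS beta and ML theta to convergence."""
    beta = np.linalg.lstsq(pb.X, pb.y, rcond=None)[0]
    vc = fit_variance_components(pb, None, beta, None, rel, model)
    prev = np.inf
    for _ in range(max_iter):
        beta = gls_coefficients(pb, rel, vc)
        # after the multi-start first fit, warm-start from the previous theta
        warm = None
        if model == "Add":
            warm = [np.array([vc.sigma2_a, vc.sigma2_e])]
        elif model == "AddDom":
            warm = [np.array([vc.sigma2_a, vc.sigma2_d, vc.sigma2_e])]
        vc = fit_variance_components(pb, None, beta, None, rel, model, starts=warm)
        core = neg_log_likelihood(pb, beta, None, None, rel, vc)
        if abs(prev - core) < tol * (1.0 + abs(core)):
            break
        prev = core
    return beta, vc
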