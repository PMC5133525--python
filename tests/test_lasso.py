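"""Penalized-objective correctness, solver soundness, and path behavior."""

import numpy as np
import pytest

from pedlasso import (
    PhenotypeBlock,
    SimulationConfig,
    VarianceComponents,
    build_covariance,
    fit_at_lambda,
    fit_path,
    lambda_grid,
    neg_log_likelihood,
    penalized_objective,
    simulate_study,
)
from pedlasso.lasso import _Workspace, _inner_lasso, kkt_residual


@pytest.fixture(scope="module")
def small_problem():
    """n = 50, S = 20 random-dosage instance with two real effects."""
    rng = np.random.default_rng(0)
    n, S = 50, 20
    Z = rng.integers(0, 3, size=(n, S)).astype(float)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = Z[:, 0] * 0.8 - Z[:, 5] * 0.5 + X @ np.array([1.0, 0.3]) + rng.normal(size=n)
    pb = PhenotypeBlock(y=y, X=X, covariate_names=["intercept", "c1"],
                        sample_order=list(range(n)))
    return pb, Z


class TestObjective:
    def test_zero_lambda_equals_likelihood_core(self, qtl_study):
        study = qtl_study
        pb = study.phenotypes(0)
        Z = study.genotypes.dosages[:, :4]
        vc = VarianceComponents(2.0, 0.0, 3.0, "Add")
        beta = np.zeros(pb.X.shape[1])
        gamma = np.array([0.5, -0.1, 0.0, 0.2])
        q = penalized_objective(pb, Z, study.rel, vc, beta, gamma, lam=0.0)
        assert q == pytest.approx(
            neg_log_likelihood(pb, beta, gamma, Z, study.rel, vc), rel=1e-12
        )

    def test_zero_gamma_equals_null_model(self, qtl_study):
        study = qtl_study
        pb = study.phenotypes(0)
        Z = study.genotypes.dosages[:, :4]
        vc = VarianceComponents(2.0, 0.0, 3.0, "Add")
        beta = np.linalg.lstsq(pb.X, pb.y, rcond=None)[0]
        q = penalized_objective(pb, Z, study.rel, vc, beta, np.zeros(4), lam=7.0)
        assert q == pytest.approx(
            neg_log_likelihood(pb, beta, None, None, study.rel, vc), rel=1e-12
        )

    def test_term_by_term_dense_oracle(self, three_gen):
        """n = 12, S = 3: matches slogdet + explicit inverse + L1, term by term."""
        from pedlasso import build_matrices

        base = build_matrices(three_gen)
        # tile the 9-member pedigree with 3 extra founders to reach n = 12
        from conftest import make_pedigree

        rows = [("GF", None, None), ("GM", None, None), ("P1", "GF", "GM"),
                ("P2", "GF", "GM"), ("S1", None, None), ("S2", None, None),
                ("C1a", "P1", "S1"), ("C1b", "P1", "S1"), ("C2", "P2", "S2"),
                ("X1", None, None), ("X2", None, None), ("X3", None, None)]
        rel = build_matrices(make_pedigree(rows))
        rng = np.random.default_rng(12)
        n, S = 12, 3
        y = rng.normal(size=n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        Z = rng.integers(0, 3, size=(n, S)).astype(float)
        pb = PhenotypeBlock(y=y, X=X, covariate_names=["i", "c"], sample_order=list(range(n)))
        beta = np.array([0.5, -1.0])
        gamma = np.array([0.3, 0.0, -0.2])
        vc = VarianceComponents(1.5, 0.7, 0.9, "AddDom")
        lam = 2.5
        got = penalized_objective(pb, Z, rel, vc, beta, gamma, lam)
        V = build_covariance(rel, vc)
        r = y - X @ beta - Z @ gamma
        want = (
            np.linalg.slogdet(V)[1]
            + float(r @ np.linalg.inv(V) @ r)
            + lam * float(np.sum(np.abs(gamma)))
        )
        assert got == pytest.approx(want, rel=1e-10)


class TestLambdaGrid:
    def test_construction(self, small_problem):
        pb, Z = small_problem
        grid = lambda_grid(pb, Z, None, "Ind", n_points=15, ratio=1e-3)
        assert len(grid) == 15
        assert np.all(np.diff(grid) < 0)
        assert grid[-1] == pytest.approx(1e-3 * grid[0])

    def test_empty_active_set_at_and_above_lambda_max(self, small_problem):
        pb, Z = small_problem
        grid = lambda_grid(pb, Z, None, "Ind", n_points=5)
        for lam in (grid[0], 1.01 * grid[0]):
            fit = fit_at_lambda(pb, Z, None, "Ind", lam)
            assert fit.active_set.size == 0

    def test_constant_column_rejected(self, small_problem):
        pb, Z = small_problem
        Zc = Z.copy()
        Zc[:, 3] = 1.0
        with pytest.raises(ValueError, match="constant"):
            lambda_grid(pb, Zc, None, "Ind")


class TestSolver:
    def test_ind_frozen_theta_matches_reference_solver(self, small_problem):
        """With Omega = 0 the whitened problem is a standard LASSO; compare
        coefficients with scikit-learn at matched penalty scaling."""
        from sklearn.linear_model import Lasso

        pb, Z = small_problem
        n = pb.n
        sig2 = 1.3
        vc = VarianceComponents(0, 0, sig2, "Ind")
        ws = _Workspace(pb, Z, None, "Ind")
        grid = lambda_grid(pb, Z, None, "Ind", n_points=10)
        for lam in grid:
            ys, Xs, Zts, _ = ws.whitened(vc)
            beta, gam, r, _ = _inner_lasso(ys, Xs, Zts, lam, np.zeros(2), np.zeros(ws.S))
            Q, _ = np.linalg.qr(Xs)
            yh, Zh = ys - Q @ (Q.T @ ys), Zts - Q @ (Q.T @ Zts)
            ref = Lasso(alpha=lam / (2 * n), fit_intercept=False, tol=1e-14,
                        max_iter=500_000).fit(Zh, yh)
            assert np.max(np.abs(ref.coef_ - gam)) < 1e-4

    def test_objective_nonincreasing_and_kkt(self, small_study):
        study = small_study
        g, rel = study.genotypes, study.rel
        for rep in range(3):
            pb = study.phenotypes(rep)
            grid = lambda_grid(pb, g.dosages[:, :30], rel, "Add", n_points=6)
            for lam in grid[::2]:
                fit = fit_at_lambda(pb, g.dosages[:, :30], rel, "Add", float(lam))
                tr = np.array(fit.objective_trace)
                assert np.all(np.diff(tr) <= 1e-7 * (1 + np.abs(tr[:-1])))
                assert fit.kkt_residual < 1e-4

    def test_solution_beats_random_perturbations(self, small_problem):
        """Q at the solution <= Q at 1000 random (beta, gamma) perturbations
        evaluated at the same theta."""
        pb, Z = small_problem
        fit = fit_at_lambda(pb, Z, None, "Ind", 8.0)
        ws = _Workspace(pb, Z, None, "Ind")
        ys, Xs, Zts, logdet = ws.whitened(fit.vc)
        # reconstruct internal beta (centering folded back out of intercept)
        beta_int = fit.beta.copy()
        beta_int[0] += ws.center @ fit.gamma
        rng = np.random.default_rng(99)
        q_star = (
            logdet
            + float(np.sum((ys - Xs @ beta_int - Zts @ fit.gamma_std) ** 2))
            + 8.0 * np.sum(np.abs(fit.gamma_std))
        )
        assert q_star == pytest.approx(fit.objective, rel=1e-8)
        B = beta_int[:, None] + rng.normal(scale=0.05, size=(2, 1000))
        G = fit.gamma_std[:, None] + rng.normal(scale=0.05, size=(ws.S, 1000))
        R = ys[:, None] - Xs @ B - Zts @ G
        q_pert = logdet + np.sum(R**2, axis=0) + 8.0 * np.sum(np.abs(G), axis=0)
        assert np.all(q_star <= q_pert + 1e-10)

    def test_column_rescaling_invariance(self, small_problem):
        pb, Z = small_problem
        lam = 10.0
        fit = fit_at_lambda(pb, Z, None, "Ind", lam)
        Z2 = Z.copy()
        Z2[:, 0] *= 10.0
        fit2 = fit_at_lambda(pb, Z2, None, "Ind", lam)
        assert np.array_equal(fit.active_set, fit2.active_set)
        assert fit2.gamma[0] == pytest.approx(fit.gamma[0] / 10.0, rel=1e-6)
        assert fit2.objective == pytest.approx(fit.objective, rel=1e-8)

    def test_negative_lambda_rejected(self, small_problem):
        pb, Z = small_problem
        with pytest.raises(ValueError):
            fit_at_lambda(pb, Z, None, "Ind", -1.0)


class TestPath:
    def test_bic_no_larger_than_aic_and_warm_monotonicity(self, small_study):
        study = small_study
        for rep in range(3):
            pb = study.phenotypes(rep)
            path = fit_path(pb, study.genotypes.dosages[:, :40], study.rel, "Add",
                            n_points=20)
            aic_size = path.selected("aic").active_set.size
            bic_size = path.selected("bic").active_set.size
            assert bic_size <= aic_size
            sizes = np.array([f.active_set.size for f in path.fits])
            assert np.mean(np.diff(sizes) >= 0) >= 0.9

    def test_df_accounting(self, small_problem):
        pb, Z = small_problem
        path = fit_path(pb, Z, None, "Ind", n_points=8)
        for f in path.fits:
            assert f.df == f.active_set.size + pb.n_covariates + 1

    def test_pure_noise_bic_mostly_empty(self):
        """Unstructured null phenotype: BIC should select nothing, usually."""
        rng = np.random.default_rng(123)
        n, S = 120, 25
        empties = 0
        for _ in range(5):
            Z = rng.integers(0, 3, size=(n, S)).astype(float)
            y = rng.normal(size=n)
            pb = PhenotypeBlock(y=y, X=np.ones((n, 1)), covariate_names=["intercept"],
                                sample_order=list(range(n)))
            path = fit_path(pb, Z, None, "Ind", n_points=20)
            empties += path.selected("bic").active_set.size == 0
        assert empties >= 3

    def test_strong_qtl_recovered(self, qtl_study):
        study = qtl_study
        truth_idx = study.genotypes.snp_map.set_index("id").index.get_indexer(
            study.truth["id"]
        )
        hits = 0
        for rep in range(3):
            pb = study.phenotypes(rep)
            path = fit_path(pb, study.genotypes.dosages, study.rel, "Add", n_points=20)
            sel = set(path.selected("bic").active_set)
            hits += set(truth_idx) <= sel
        assert hits >= 2

    def test_objective_recomputable_from_parts(self, small_problem):
        pb, Z = small_problem
        path = fit_path(pb, Z, None, "Ind", n_points=6)
        for f in path.fits:
            core = -2.0 * f.loglik - pb.n * np.log(2 * np.pi)
            assert f.objective == pytest.approx(
                core + f.lam * np.sum(np.abs(f.gamma_std)), rel=1e-8
            )
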