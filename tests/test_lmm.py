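"""Mixed-model core: covariance assembly, likelihood, whitening, VC fitting."""

import numpy as np
import pytest

from pedlasso import (
    PhenotypeBlock,
    SimulationConfig,
    VarianceComponents,
    build_covariance,
    build_matrices,
    fit_null_model,
    fit_variance_components,
    neg_log_likelihood,
    read_phenotypes,
    simulate_study,
    whiten,
)
from pedlasso.lmm import get_structure

from conftest import make_pedigree


def make_block(y, X=None, names=None):
    y = np.asarray(y, dtype=float)
    if X is None:
        X = np.ones((len(y), 1))
        names = ["intercept"]
    return PhenotypeBlock(y=y, X=X, covariate_names=names, sample_order=list(range(len(y))))


@pytest.fixture
def nuclear_rel(nuclear):
    return build_matrices(nuclear)


class TestVarianceComponents:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(sigma2_a=-1, sigma2_d=0, sigma2_e=1, model="AddDom"),
            dict(sigma2_a=1, sigma2_d=0, sigma2_e=0, model="Add"),
            dict(sigma2_a=1, sigma2_d=0.5, sigma2_e=1, model="Add"),
            dict(sigma2_a=0.1, sigma2_d=0, sigma2_e=1, model="Ind"),
            dict(sigma2_a=1, sigma2_d=0, sigma2_e=1, model="Weird"),
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            VarianceComponents(**kwargs)


class TestBuildCovariance:
    def test_ind_is_scaled_identity(self, nuclear_rel):
        vc = VarianceComponents(0, 0, 1.0, "Ind")
        assert np.array_equal(build_covariance(nuclear_rel, vc), np.eye(4))

    def test_unrelated_founders_diagonal(self):
        ped = make_pedigree([(f"f{i}", None, None) for i in range(6)])
        rel = build_matrices(ped)
        vc = VarianceComponents(3.0, 0.0, 2.0, "Add")
        assert np.allclose(build_covariance(rel, vc), 5.0 * np.eye(6))

    def test_nuclear_family_hand_arithmetic(self, nuclear_rel):
        vc = VarianceComponents(2.0, 1.0, 1.0, "AddDom")
        V = build_covariance(nuclear_rel, vc)
        i = {k[1]: j for j, k in enumerate(nuclear_rel.sample_order)}
        # sib pair: 2*0.25*2 + 0.25*1 = 1.25
        assert V[i["C1"], i["C2"]] == pytest.approx(1.25)
        # parent-child: 2*0.25*2 + 0 = 1.0; diagonal: 2*0.5*2 + 1 + 1 = 4
        assert V[i["F"], i["C1"]] == pytest.approx(1.0)
        assert V[i["C1"], i["C1"]] == pytest.approx(4.0)

    def test_linear_in_each_component(self, nuclear_rel):
        v1 = build_covariance(nuclear_rel, VarianceComponents(1, 0, 1, "AddDom"))
        v2 = build_covariance(nuclear_rel, VarianceComponents(3, 0, 1, "AddDom"))
        v0 = build_covariance(nuclear_rel, VarianceComponents(0, 0, 1, "AddDom"))
        assert np.allclose(v2 - v0, 3 * (v1 - v0))

    def test_model_mismatch_rejected(self, nuclear_rel):
        struct = get_structure(nuclear_rel, "AddDom")
        with pytest.raises(ValueError, match="model"):
            struct.nll_core(VarianceComponents(1, 0, 1, "Add"), np.zeros(4))


class TestLikelihood:
    def test_identity_covariance_cases(self):
        pb = make_block(np.zeros(5))
        vc = VarianceComponents(0, 0, 1.0, "Ind")
        beta = np.zeros(1)
        assert neg_log_likelihood(pb, beta, None, None, None, vc) == pytest.approx(0.0)
        r = np.array([1.0, 2.0, 0.0, 0.0, 0.0])  # sum of squares 5
        pb2 = make_block(r)
        assert neg_log_likelihood(pb2, beta, None, None, None, vc) == pytest.approx(5.0)

    def test_dense_oracle_small_instance(self, three_gen):
        """Cholesky/spectral evaluation matches explicit inverse + slogdet."""
        rel = build_matrices(three_gen).subset(build_matrices(three_gen).sample_order[:8])
        rng = np.random.default_rng(5)
        y = rng.normal(size=8)
        X = np.column_stack([np.ones(8), rng.normal(size=8)])
        Z = rng.integers(0, 3, size=(8, 2)).astype(float)
        beta, gamma = np.array([0.4, -0.2]), np.array([0.7, 0.1])
        pb = PhenotypeBlock(y=y, X=X, covariate_names=["i", "c"], sample_order=list(range(8)))
        for vc in [
            VarianceComponents(1.3, 0.6, 0.8, "AddDom"),
            VarianceComponents(2.0, 0.0, 0.5, "Add"),
            VarianceComponents(0.0, 0.0, 1.7, "Ind"),
        ]:
            got = neg_log_likelihood(pb, beta, gamma, Z, rel, vc)
            V = build_covariance(rel, vc)
            r = y - X @ beta - Z @ gamma
            want = np.linalg.slogdet(V)[1] + r @ np.linalg.inv(V) @ r
            assert got == pytest.approx(want, rel=1e-10)

    def test_permutation_invariance(self, qtl_study):
        study = qtl_study
        pb = study.phenotypes(0)
        Z = study.genotypes.dosages[:, :3]
        vc = VarianceComponents(2.0, 0.0, 3.0, "Add")
        beta = np.zeros(pb.X.shape[1])
        gamma = np.array([0.5, -0.2, 0.1])
        base = neg_log_likelihood(pb, beta, gamma, Z, study.rel, vc)
        rng = np.random.default_rng(1)
        perm = rng.permutation(pb.n)
        pb_p = PhenotypeBlock(
            y=pb.y[perm], X=pb.X[perm], covariate_names=pb.covariate_names,
            sample_order=[pb.sample_order[i] for i in perm],
        )
        rel_p = study.rel.subset([study.rel.sample_order[i] for i in perm])
        got = neg_log_likelihood(pb_p, beta, gamma, Z[perm], rel_p, vc)
        assert got == pytest.approx(base, rel=1e-10)

    @pytest.mark.parametrize("model", ["Add", "AddDom"])
    def test_singular_covariance_raises(self, nuclear_rel, model):
        # duplicating a sample makes Omega singular; with sigma2_e = 0 the
        # decomposition must fail loudly, naming theta
        dup = nuclear_rel.subset([nuclear_rel.sample_order[0]] * 2)
        struct = get_structure(dup, model)
        vc = VarianceComponents.__new__(VarianceComponents)
        vc.sigma2_a, vc.sigma2_d, vc.sigma2_e, vc.model = 1.0, 0.0, 0.0, model
        with pytest.raises(np.linalg.LinAlgError, match="positive definite"):
            struct.nll_core(vc, np.ones(2))


class TestWhitening:
    def test_identity_whitening_is_noop(self):
        pb = make_block(np.array([1.0, -2.0, 0.5]))
        Z = np.array([[0.0], [1.0], [2.0]])
        vc = VarianceComponents(0, 0, 1.0, "Ind")
        ys, Xs, Zs = whiten(pb, Z, None, vc)
        assert np.allclose(ys, pb.y) and np.allclose(Xs, pb.X) and np.allclose(Zs, Z)

    @pytest.mark.parametrize("model", ["Add", "AddDom"])
    def test_quadratic_form_identity(self, three_gen, model):
        rel = build_matrices(three_gen).subset(build_matrices(three_gen).sample_order[:6])
        rng = np.random.default_rng(3)
        y = rng.normal(size=6)
        X = np.column_stack([np.ones(6), rng.normal(size=6)])
        Z = rng.integers(0, 3, size=(6, 2)).astype(float)
        pb = PhenotypeBlock(y=y, X=X, covariate_names=["i", "c"], sample_order=list(range(6)))
        vc = (
            VarianceComponents(1.1, 0.4, 0.6, "AddDom")
            if model == "AddDom"
            else VarianceComponents(1.1, 0.0, 0.6, "Add")
        )
        beta, gamma = np.array([0.2, 0.9]), np.array([-0.3, 0.5])
        ys, Xs, Zs = whiten(pb, Z, rel, vc)
        lhs = np.sum((ys - Xs @ beta - Zs @ gamma) ** 2)
        V = build_covariance(rel, vc)
        r = y - X @ beta - Z @ gamma
        assert lhs == pytest.approx(r @ np.linalg.inv(V) @ r, rel=1e-10)


class TestVarianceFitting:
    def test_ind_closed_form(self):
        rng = np.random.default_rng(0)
        y = rng.normal(scale=2.0, size=200)
        pb = make_block(y)
        beta = np.array([y.mean()])
        vc = fit_variance_components(pb, None, beta, None, None, "Ind")
        assert vc.sigma2_e == pytest.approx(np.mean((y - y.mean()) ** 2), abs=1e-8)

    def test_add_recovery_small(self):
        """Mean sigma2_a over seeded replicates near the generating value."""
        cfg = SimulationConfig(seed=17, n_families=10, n_snps=10, n_qtls=0,
                               sigma2_a=4.0, sigma2_e=4.0)
        study = simulate_study(cfg)
        est = []
        for r in range(12):
            pb = study.phenotypes(r)
            _, vc = fit_null_model(pb, study.rel, "Add")
            est.append(vc.sigma2_a)
        assert np.mean(est) == pytest.approx(4.0, rel=0.25)

    def test_dominance_detected_when_present(self):
        cfg = SimulationConfig(seed=19, n_families=10, n_snps=10, n_qtls=0,
                               sigma2_a=0.0, sigma2_d=4.0, sigma2_e=4.0)
        study = simulate_study(cfg)
        hits = 0
        for r in range(6):
            pb = study.phenotypes(r)
            _, vc = fit_null_model(pb, study.rel, "AddDom")
            hits += vc.sigma2_d > 0.5
        assert hits >= 4

    def test_unknown_model_rejected(self):
        pb = make_block(np.arange(4.0))
        with pytest.raises(ValueError):
            fit_variance_components(pb, None, np.zeros(1), None, None, "Huh")


def test_phenotype_tsv_round_trip(tmp_path):
    import pandas as pd

    df = pd.DataFrame(
        {"id": ["a", "b", "c", "d"], "sbp": [120.0, 131.5, 110.2, 140.0],
         "age": [40, 50, 60, 45], "smoke": [0, 1, 0, 1]}
    )
    df.to_csv(tmp_path / "ph.tsv", sep="\t", index=False)
    pb = read_phenotypes(tmp_path / "ph.tsv")
    assert pb.covariate_names == ["intercept", "age", "smoke"]
    assert np.allclose(pb.X[:, 0], 1.0)
    assert np.allclose(pb.y, df["sbp"])
    pb_sub = read_phenotypes(tmp_path / "ph.tsv", sample_subset=["c", "a", "b"])
    assert pb_sub.sample_order == ["c", "a", "b"]
    assert pb_sub.y[0] == pytest.approx(110.2)


def test_rank_deficient_covariates_rejected():
    y = np.arange(5.0)
    X = np.column_stack([np.ones(5), np.ones(5)])
    with pytest.raises(ValueError, match="rank"):
        PhenotypeBlock(y=y, X=X, covariate_names=["a", "b"], sample_order=list(range(5)))
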