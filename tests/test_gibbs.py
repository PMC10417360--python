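import numpy as np
import pandas as pd
import pytest

from gibbsam.gibbs import (ChainConfig, GibbsSampler, run_chain,
                           sample_genetic_covariance, sample_residual)
from gibbsam.pedigree import Pedigree
from gibbsam.phenotypes import BivariateModelSpec, TraitModel, build_design

from conftest import make_halfsib_data


def _founder_design(n=40, var2_scale=2.0, seed=0):
    """Both traits recorded on n unrelated founders, intercept-only."""
    rng = np.random.default_rng(seed)
    ped = Pedigree.from_records([(i, 0, 0) for i in range(1, n + 1)])
    pheno = pd.DataFrame({
        "animal": np.arange(1, n + 1),
        "t1": rng.normal(1.0, 1.0, n),
        "t2": rng.normal(5.0, var2_scale, n),
    })
    spec = BivariateModelSpec(TraitModel("t1"), TraitModel("t2"))
    return build_design(ped, pheno, spec)


class TestChainConfig:
    def test_burn_in_must_precede_end(self):
        with pytest.raises(ValueError, match="burn-in"):
            ChainConfig(iterations=100, burn_in=100)

    def test_lag_must_be_positive(self):
        with pytest.raises(ValueError, match="lag"):
            ChainConfig(iterations=100, burn_in=10, lag=0)

    def test_retained_count_arithmetic(self):
        cfg = ChainConfig.desk()
        assert (cfg.iterations, cfg.burn_in, cfg.lag) == (20000, 4000, 4)
        assert cfg.n_retained == 4000
        assert ChainConfig(iterations=1001, burn_in=100, lag=7).n_retained \
            == (1001 - 100) // 7


class TestInitialisation:
    def test_starting_components_half_phenotypic_variance(self):
        design = _founder_design()
        v1 = np.var(design.t1.y)
        v2 = np.var(design.t2.y)
        s = GibbsSampler(design, ChainConfig(iterations=10, burn_in=1))
        G, R = s.initial_components()
        np.testing.assert_allclose(np.diag(G), [0.5 * v1, 0.5 * v2])
        np.testing.assert_allclose(np.diag(R), [0.5 * v1, 0.5 * v2])
        assert G[0, 1] == 0.0 and R[0, 1] == 0.0

    def test_zero_variance_trait_rejected(self):
        ped = Pedigree.from_records([(i, 0, 0) for i in range(1, 6)])
        pheno = pd.DataFrame({"animal": range(1, 6),
                              "t1": np.ones(5),
                              "t2": np.arange(5.0)})
        design = build_design(ped, pheno, BivariateModelSpec(
            TraitModel("t1"), TraitModel("t2")))
        with pytest.raises(ValueError, match="zero phenotypic variance"):
            GibbsSampler(design, ChainConfig(iterations=10, burn_in=1))


class TestLocationSampler:
    def test_posterior_mean_of_general_mean(self):
        # With a vanishing genetic variance the general-mean draw reduces
        # to the conjugate normal: mu | y ~ N(ybar, sigma_e^2 / n).
        design = _founder_design(n=50)
        s = GibbsSampler(design, ChainConfig(iterations=10, burn_in=1))
        G = np.diag([1e-8, 1e-8])
        R = np.diag([1.0, 4.0])
        rng = np.random.default_rng(1)
        draws = np.array([s.sample_location(G, R, rng)[0][0]
                          for _ in range(4000)])
        se = np.sqrt(R[0, 0] / design.t1.n_records)
        assert draws.mean() == pytest.approx(design.t1.y.mean(),
                                             abs=4 * se / np.sqrt(4000))
        assert draws.std() == pytest.approx(se, rel=0.1)

    def test_unrecorded_animal_draws_from_prior(self):
        # A founder without data and unrelated to the recorded animals
        # has full conditional equal to its prior N(0, G).
        ped = Pedigree.from_records([(1, 0, 0), (2, 0, 0), (3, 0, 0)])
        pheno = pd.DataFrame({"animal": [1, 2], "t1": [0.3, -0.2],
                              "t2": [1.0, 2.0]})
        design = build_design(ped, pheno, BivariateModelSpec(
            TraitModel("t1"), TraitModel("t2")))
        s = GibbsSampler(design, ChainConfig(iterations=10, burn_in=1))
        G = np.array([[0.5, 0.2], [0.2, 1.0]])
        R = np.diag([1.0, 1.0])
        rng = np.random.default_rng(2)
        i3 = ped.index_of([3])[0]
        draws = np.array([np.array(s.sample_location(G, R, rng)[2:])[:, i3]
                          for _ in range(4000)])
        cov = np.cov(draws.T)
        np.testing.assert_allclose(cov, G, atol=4 * 1.0 / np.sqrt(4000))
        np.testing.assert_allclose(draws.mean(0), [0, 0],
                                   atol=4 * np.sqrt(G[1, 1] / 4000))

    def test_matches_dense_full_conditional_on_small_pedigree(self):
        # Brute-force oracle: assemble the joint precision of all
        # location parameters densely, invert it, and compare moments.
        ped = Pedigree.from_records(
            [(1, 0, 0), (2, 0, 0), (3, 1, 2), (4, 1, 2), (5, 3, 2)])
        pheno = pd.DataFrame({
            "animal": [1, 3, 4, 5],
            "t1": [2.0, 1.5, 0.7, 2.2],
            "t2": [np.nan, 3.0, 2.5, 1.0],
            "batch": [1, 1, 2, 2],
            "grp": [np.nan, 1, 2, 1],
        })
        spec = BivariateModelSpec(TraitModel("t1", ("batch",)),
                                  TraitModel("t2", ("grp",)))
        design = build_design(ped, pheno, spec)
        assert design.residual_free
        G = np.array([[1.0, 0.4], [0.4, 2.0]])
        R = np.array([[0.8, 0.3], [0.3, 1.5]])
        s = GibbsSampler(design, ChainConfig(iterations=10, burn_in=1))

        q = ped.n
        t1, t2 = design.t1, design.t2
        p1, p2 = t1.X.shape[1], t2.X.shape[1]
        n1, n2 = t1.n_records, t2.n_records
        Z1 = np.zeros((n1, q)); Z1[np.arange(n1), t1.animal_rows] = 1
        Z2 = np.zeros((n2, q)); Z2[np.arange(n2), t2.animal_rows] = 1
        W = np.block([
            [t1.X.toarray(), np.zeros((n1, p2)), Z1, np.zeros((n1, q))],
            [np.zeros((n2, p1)), t2.X.toarray(), np.zeros((n2, q)), Z2]])
        Rbig = np.zeros((n1 + n2, n1 + n2))
        pos1 = {a: i for i, a in enumerate(t1.animal_rows)}
        for i in range(n1):
            Rbig[i, i] = R[0, 0]
        for j, a in enumerate(t2.animal_rows):
            Rbig[n1 + j, n1 + j] = R[1, 1]
            if a in pos1:
                Rbig[pos1[a], n1 + j] = Rbig[n1 + j, pos1[a]] = R[0, 1]
        Rinv = np.linalg.inv(Rbig)
        Ainv = np.linalg.inv(ped.a_matrix_tabular().toarray())
        prior = np.zeros((p1 + p2 + 2 * q,) * 2)
        prior[p1 + p2:, p1 + p2:] = np.kron(np.linalg.inv(G), Ainv)
        C = W.T @ Rinv @ W + prior
        y = np.concatenate([t1.y, t2.y])
        mean = np.linalg.solve(C, W.T @ Rinv @ y)
        cov = np.linalg.inv(C)

        rng = np.random.default_rng(42)
        N = 12000
        draws = np.empty((N, C.shape[0]))
        for k in range(N):
            b1, b2, a1, a2 = s.sample_location(G, R, rng)
            draws[k] = np.concatenate([b1, b2, a1, a2])
        sd = np.sqrt(np.diag(cov))
        np.testing.assert_allclose(draws.mean(0), mean,
                                   atol=4 * sd.max() / np.sqrt(N))
        assert np.abs(np.cov(draws.T) - cov).max() < 0.05 * np.abs(cov).max()


class TestCovarianceSamplers:
    @pytest.mark.parametrize("convention,denom", [("q", lambda q: q - 3),
                                                  ("flat", lambda q: q - 6)])
    def test_genetic_covariance_inverse_wishart_moment(self, convention,
                                                       denom):
        # A = I (independent founders): S_a = a'a, and the conditional
        # mean of G is S_a / (df - 3) with df = q or q - 3.
        q = 10
        ped = Pedigree.from_records([(i, 0, 0) for i in range(1, q + 1)])
        ainv = ped.a_inverse()
        a1 = np.sqrt(10.0 / q) * np.ones(q)
        a2 = np.zeros(q); a2[: q // 2] = np.sqrt(20.0 / q)
        S = np.array([[a1 @ a1, a1 @ a2], [a1 @ a2, a2 @ a2]])
        rng = np.random.default_rng(3)
        draws = np.array([sample_genetic_covariance(a1, a2, ainv, rng,
                                                    convention)
                          for _ in range(20000)])
        expect = S / denom(q)
        se = draws.std(axis=0) / np.sqrt(len(draws))
        assert np.all(np.abs(draws.mean(0) - expect) < 4 * se)

    def test_genetic_covariance_permutation_invariance(self):
        rng = np.random.default_rng(4)
        ped = Pedigree.from_records(
            [(1, 0, 0), (2, 0, 0), (3, 1, 2), (4, 1, 2), (5, 3, 4)])
        ainv = ped.a_inverse()
        a1 = rng.normal(size=5)
        a2 = rng.normal(size=5)
        perm = rng.permutation(5)
        P = np.eye(5)[perm]
        ainv_p = type(ainv)(csr=__import__("scipy.sparse", fromlist=["x"])
                            .csr_matrix(P @ ainv.toarray() @ P.T))
        g_ref = sample_genetic_covariance(a1, a2, ainv,
                                          np.random.default_rng(99))
        g_perm = sample_genetic_covariance(a1[perm], a2[perm], ainv_p,
                                           np.random.default_rng(99))
        np.testing.assert_allclose(g_ref, g_perm, rtol=1e-10)

    def test_uncorrelated_breeding_values_give_zero_mean_offdiagonal(self):
        q = 200
        ped = Pedigree.from_records([(i, 0, 0) for i in range(1, q + 1)])
        ainv = ped.a_inverse()
        rng = np.random.default_rng(5)
        a1 = rng.normal(size=q)
        a2 = rng.normal(size=q)
        a2 -= (a1 @ a2) / (a1 @ a1) * a1  # exactly orthogonal
        draws = np.array([sample_genetic_covariance(a1, a2, ainv, rng)[0, 1]
                          for _ in range(5000)])
        assert abs(draws.mean()) < 4 * draws.std() / np.sqrt(len(draws))

    @pytest.mark.parametrize("convention,denom", [("q", 48), ("flat", 46)])
    def test_residual_scaled_inverse_chi_square_moment(self, convention,
                                                       denom):
        # scale e'e = 100, n = 50: conditional mean e'e/(df - 2) with
        # df = n ("q") or n - 2 (flat-prior conditional)
        n = 50
        e1 = np.sqrt(100.0 / n) * np.ones(n)
        e2 = np.ones(n)
        rng = np.random.default_rng(6)
        draws = np.array([sample_residual(e1, e2, None, False, rng,
                                          convention)[0, 0]
                          for _ in range(20000)])
        se = draws.std() / np.sqrt(len(draws))
        assert draws.mean() == pytest.approx(100.0 / denom, abs=4 * se)

    def test_residual_free_recovers_high_correlation(self):
        rng = np.random.default_rng(7)
        n = 2000
        L = np.linalg.cholesky(np.array([[1.0, 0.9], [0.9, 1.0]]))
        E = rng.standard_normal((n, 2)) @ L.T
        joint = (np.arange(n), np.arange(n))
        draws = np.array([sample_residual(E[:, 0], E[:, 1], joint, True, rng)
                          for _ in range(2000)])
        corr = draws[:, 0, 1] / np.sqrt(draws[:, 0, 0] * draws[:, 1, 1])
        assert corr.mean() == pytest.approx(
            np.corrcoef(E.T)[0, 1], abs=0.02)

    def test_disjoint_residual_covariance_exactly_zero(self):
        rng = np.random.default_rng(8)
        R = sample_residual(rng.normal(size=30), rng.normal(size=40),
                            None, False, rng)
        assert R[0, 1] == 0.0 and R[1, 0] == 0.0


class TestRunChain:
    def test_retained_count_and_determinism(self, rng):
        ped, pheno = make_halfsib_data(rng, 20, 5,
                                       G=np.diag([0.4, 0.4]),
                                       R=np.diag([0.6, 0.6]))
        spec = BivariateModelSpec(TraitModel("t1"), TraitModel("t2"))
        design = build_design(ped, pheno, spec)
        cfg = ChainConfig(iterations=600, burn_in=100, lag=5, seed=11)
        s1 = run_chain(design, cfg)
        s2 = run_chain(design, cfg)
        assert len(s1) == cfg.n_retained == 100
        pd.testing.assert_frame_equal(s1.samples, s2.samples)
        s3 = run_chain(design, ChainConfig(iterations=600, burn_in=100,
                                           lag=5, seed=12))
        assert not s3.samples.equals(s1.samples)

    def test_every_retained_g_is_positive_definite(self, rng):
        ped, pheno = make_halfsib_data(rng, 15, 4,
                                       G=np.array([[0.4, 0.2], [0.2, 0.4]]),
                                       R=np.diag([0.6, 0.6]))
        design = build_design(ped, pheno, BivariateModelSpec(
            TraitModel("t1"), TraitModel("t2")))
        store = run_chain(design, ChainConfig(iterations=400, burn_in=100,
                                              lag=2, seed=13))
        g11, g12, g22 = store["G11"], store["G12"], store["G22"]
        assert np.all(g11 > 0) and np.all(g22 > 0)
        assert np.all(g11 * g22 - g12 ** 2 > 0)
        assert np.all(np.abs(store["rg"]) < 1)
        np.testing.assert_allclose(
            store["h2_t1"], g11 / (g11 + store["R11"]), rtol=1e-12)

    def test_disjoint_run_keeps_residual_covariance_at_zero(self, rng):
        # Split the half-sib offspring so each trait is recorded on a
        # different half: the residual covariance must stay bit-zero.
        ped, pheno = make_halfsib_data(rng, 20, 6,
                                       G=np.diag([0.4, 0.4]),
                                       R=np.diag([0.6, 0.6]))
        half = len(pheno) // 2
        pheno = pheno.copy()
        pheno.loc[pheno.index[:half], "t2"] = np.nan
        pheno.loc[pheno.index[half:], "t1"] = np.nan
        design = build_design(ped, pheno, BivariateModelSpec(
            TraitModel("t1"), TraitModel("t2")))
        assert design.residual_free is False
        store = run_chain(design, ChainConfig(iterations=500, burn_in=100,
                                              lag=2, seed=14))
        assert np.all(store["R12"] == 0.0)

    def test_samples_file_round_trip(self, rng, tmp_path):
        from gibbsam.gibbs import SampleStore
        ped, pheno = make_halfsib_data(rng, 10, 4,
                                       G=np.diag([0.4, 0.4]),
                                       R=np.diag([0.6, 0.6]))
        design = build_design(ped, pheno, BivariateModelSpec(
            TraitModel("t1"), TraitModel("t2")))
        path = tmp_path / "samples.csv"
        store = run_chain(design, ChainConfig(iterations=300, burn_in=100,
                                              lag=2, seed=15),
                          samples_path=path)
        back = SampleStore.load(path)
        assert len(back) == len(store)
        np.testing.assert_allclose(back["rg"], store["rg"], rtol=1e-9)
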